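"""Composite interval mapping (CIM) by Haley-Knott-style regression.

At each test position on a 1-cM grid the trait is regressed on the expected
QTL genotype given the flanking markers, with up to ``n_cofactors``
background markers (chosen by stepwise regression) as covariates; cofactors
within the blockout ``window`` of the test position on the same chromosome
are excluded.  The LOD score is ``(n/2) * log10(RSS0 / RSS1)`` comparing the
covariate-only model with the model including the position predictor.

For a fully inbred (two-class, +-1 coded) population the conditional
expectation of the QTL code given flanking markers is *linear* in the two
marker codes, so the whole predictor grid is a sparse linear map of the
genotype matrix; scans reuse that precomputation across bootstrap
replicates (resampling rows of the predictor matrix) and permutations
(which leave it untouched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import math

import numpy as np
from scipy import special

from qtlci.genmap import GeneticMap, MarkerLocus, haldane_recomb, ril_expand
from qtlci.popsim import SimulatedDataset

__all__ = [
    "ScanSettings",
    "CofactorSet",
    "LODCurve",
    "ScanPlan",
    "regression_lod",
    "conditional_expectation",
    "stepwise_cofactors",
    "cim_scan",
    "build_scan_plan",
    "LOD_CAP",
]

#: LOD value reported when the full model fits perfectly (RSS1 = 0).
LOD_CAP = 1e6

_RANK_TOL = 1e-9


@dataclass(frozen=True)
class ScanSettings:
    """Tunable CIM parameters.

    walk
        spacing of test positions, cM (1.0).
    window
        blockout half-width, cM: cofactors on the test chromosome within
        ``window`` of the test position are dropped from the model (10.0).
    n_cofactors
        maximum number of background markers used in any scan (5).
    p_entry
        partial-F significance level for stepwise entry/removal (0.05).
    max_forward_steps
        hard bound on forward additions during stepwise selection (10).
    """

    walk: float = 1.0
    window: float = 10.0
    n_cofactors: int = 5
    p_entry: float = 0.05
    max_forward_steps: int = 10

    def __post_init__(self) -> None:
        if self.walk <= 0:
            raise ValueError(f"walk must be > 0, got {self.walk}")
        if self.window < 0:
            raise ValueError(f"window must be >= 0, got {self.window}")
        if not 0.0 < self.p_entry < 1.0:
            raise ValueError(f"p_entry must be in (0, 1), got {self.p_entry}")
        if self.n_cofactors < 0 or self.max_forward_steps < 0:
            raise ValueError("n_cofactors and max_forward_steps must be >= 0")


@dataclass(frozen=True)
class CofactorSet:
    """Background markers in stepwise entry order.

    ``indices`` are flat column indices into the dataset genotype matrix,
    parallel to ``markers``.  At most the first ``n_cofactors`` entries are
    used in a scan.
    """

    markers: tuple[MarkerLocus, ...]
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.indices):
            raise ValueError("markers and indices must be parallel")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("duplicate cofactors")

    def __len__(self) -> int:
        return len(self.markers)

    def head(self, k: int) -> "CofactorSet":
        return CofactorSet(self.markers[:k], self.indices[:k])


@dataclass(frozen=True)
class LODCurve:
    """LOD profile of one chromosome on the scan grid."""

    chromosome_id: int
    grid: np.ndarray
    lod: np.ndarray
    n_covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        l = np.asarray(self.lod, dtype=float)
        if g.shape != l.shape:
            raise ValueError("grid and lod must have equal length")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "lod", l)

    def peak(self) -> tuple[float, float]:
        """(position, height) of the leftmost maximum."""
        i = int(np.argmax(self.lod))
        return float(self.grid[i]), float(self.lod[i])


def _orthonormal_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of C (rank-revealing)."""
    U, s, _ = np.linalg.svd(C, full_matrices=False)
    tol = s.max(initial=0.0) * max(C.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    return U[:, :rank]


def regression_lod(y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None) -> float:
    """LOD score for adding predictor ``x`` to an intercept+covariates model.

    ``LOD = (n/2) * log10(RSS0 / RSS1)`` where RSS0 is the residual sum of
    squares of y on the covariates (plus intercept) and RSS1 additionally
    includes x.  Collinear covariates are dropped (with a warning); a perfect
    fit returns :data:`LOD_CAP`.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    cols = [np.ones((n, 1))]
    if covariates is not None and np.size(covariates) > 0:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    C = np.concatenate(cols, axis=1)
    U = _orthonormal_basis(C)
    if U.shape[1] < C.shape[1]:
        warnings.warn("rank-deficient covariate design; collinear columns dropped")
    if n <= U.shape[1] + 2:
        raise ValueError(f"need n > #covariates + 2, got n={n}")
    y_res = y - U @ (U.T @ y)
    rss0 = float(y_res @ y_res)
    x_res = x - U @ (U.T @ x)
    den = float(x_res @ x_res)
    if den <= _RANK_TOL * n:
        return 0.0
    rss1 = rss0 - float(x_res @ y_res) ** 2 / den
    if rss1 <= 0.0:
        return LOD_CAP
    return float(min(max((n / 2.0) * np.log10(rss0 / rss1), 0.0), LOD_CAP))


def conditional_expectation(mL: float, mR: float, dL: float, dR: float) -> float:
    """Expected +-1 QTL code given flanking-marker codes and cM distances.

    Uses the two-interval Markov chain on RI1-expanded recombination
    fractions R1 (left), R2 (right): the chance the flanking markers agree is
    1 - R12 with R12 = R1 + R2 - 2 R1 R2, and

    ``P(Q = mL class | mL = mR)  = (1-R1)(1-R2) / (1-R12)``
    ``P(Q = mL class | mL != mR) = (1-R1) R2 / R12``

    The returned expectation is ``(+1) P(Q=+1|.) + (-1) P(Q=-1|.)``.
    """
    if dL < 0 or dR < 0:
        raise ValueError("flanking distances must be >= 0 cM")
    if mL not in (-1, 1) or mR not in (-1, 1):
        raise ValueError("marker codes must be +1 or -1")
    if dL == 0 and dR == 0:
        if mL != mR:
            raise ValueError("coincident flanking markers with conflicting genotypes")
        return float(mL)
    alpha, beta = _flanking_coefficients(dL, dR)
    return float(alpha * mL + beta * mR)


def _flanking_coefficients(dL: float, dR: float) -> tuple[float, float]:
    """(alpha, beta) such that E[Q | mL, mR] = alpha*mL + beta*mR.

    Linearity holds because flipping both marker codes flips the
    expectation; alpha and beta are the half-sum and half-difference of the
    matched and mismatched conditional expectations.
    """
    if dL == 0:
        return 1.0, 0.0
    if dR == 0:
        return 0.0, 1.0
    r1 = ril_expand(haldane_recomb(dL))
    r2 = ril_expand(haldane_recomb(dR))
    r12 = r1 + r2 - 2.0 * r1 * r2
    e_same = 2.0 * (1.0 - r1) * (1.0 - r2) / (1.0 - r12) - 1.0
    e_diff = 2.0 * (1.0 - r1) * r2 / r12 - 1.0
    return 0.5 * (e_same + e_diff), 0.5 * (e_same - e_diff)


@dataclass(frozen=True)
class ScanPlan:
    """Precomputed scan geometry for one map at one walking speed.

    ``left``/``right`` are flat marker-column indices of the flanking
    markers of every grid point; ``alpha``/``beta`` the linear coefficients
    of the conditional-expectation predictor; ``chrom_id``/``position``
    label the grid; ``chrom_slices`` delimit each chromosome's grid block.
    """

    chrom_id: np.ndarray
    position: np.ndarray
    left: np.ndarray
    right: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    chrom_slices: tuple[tuple[int, int, int], ...]  # (chromosome_id, start, stop)
    marker_chrom: np.ndarray
    marker_pos: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.position.shape[0]

    def predictors(self, genotypes: np.ndarray) -> np.ndarray:
        """n x n_positions matrix of conditional-expectation predictors."""
        G = np.asarray(genotypes, dtype=float)
        return G[:, self.left] * self.alpha + G[:, self.right] * self.beta


def build_scan_plan(gmap: GeneticMap, walk: float = 1.0) -> ScanPlan:
    """Lay out the test-position grid and flanking-marker algebra for a map.

    The grid covers [0, length] of every chromosome inclusive at ``walk`` cM
    spacing (166 points for a 165-cM chromosome at 1 cM).  Positions outside
    the marker span condition on the single nearest marker.
    """
    if walk <= 0:
        raise ValueError(f"walk must be > 0, got {walk}")
    chrom_ids, positions, lefts, rights, alphas, betas, slices = [], [], [], [], [], [], []
    offset = 0
    start = 0
    for chrom in gmap.chromosomes:
        mpos = np.asarray(chrom.positions, dtype=float)
        n_steps = int(round(chrom.length / walk))
        grid = np.minimum(np.arange(n_steps + 1) * walk, chrom.length)
        for p in grid:
            iL = int(np.searchsorted(mpos, p, side="right")) - 1
            iR = int(np.searchsorted(mpos, p, side="left"))
            if iL < 0:  # left of the first marker: one-sided conditioning
                j = offset + 0
                r = ril_expand(haldane_recomb(mpos[0] - p))
                a, b = 0.0, 1.0 - 2.0 * r
                iL = 0
            elif iR >= len(mpos):  # right of the last marker
                j = offset + len(mpos) - 1
                r = ril_expand(haldane_recomb(p - mpos[-1]))
                a, b = 1.0 - 2.0 * r, 0.0
                iR = len(mpos) - 1
            else:
                a, b = _flanking_coefficients(p - mpos[iL], mpos[iR] - p)
            chrom_ids.append(chrom.chromosome_id)
            positions.append(p)
            lefts.append(offset + iL)
            rights.append(offset + iR)
            alphas.append(a)
            betas.append(b)
        slices.append((chrom.chromosome_id, start, start + len(grid)))
        start += len(grid)
        offset += len(mpos)
    marker_chrom = np.array([m.chromosome_id for m in gmap.marker_table()])
    marker_pos = np.array([m.position for m in gmap.marker_table()])
    return ScanPlan(
        np.array(chrom_ids),
        np.array(positions, dtype=float),
        np.array(lefts),
        np.array(rights),
        np.array(alphas, dtype=float),
        np.array(betas, dtype=float),
        tuple(slices),
        marker_chrom,
        marker_pos,
    )


def _active_cofactor_masks(
    plan: ScanPlan, cof_indices: np.ndarray, settings: ScanSettings
) -> np.ndarray:
    """Boolean (n_positions, n_cof) matrix: cofactor j usable at position i.

    A cofactor is blocked if it lies on the same chromosome as the test
    position and within ``window`` cM of it (boundary inclusive), or if it
    is one of the two flanking markers of the test position.  The flanking
    markers span the position predictor ``x = alpha*mL + beta*mR``, so
    leaving either in the covariate set would absorb the very signal being
    tested; they are excluded at any window size.  Cofactors on other
    chromosomes are never blocked.
    """
    if cof_indices.size == 0:
        return np.zeros((plan.n_positions, 0), dtype=bool)
    same = plan.chrom_id[:, None] == plan.marker_chrom[cof_indices][None, :]
    near = np.abs(plan.position[:, None] - plan.marker_pos[cof_indices][None, :]) <= settings.window
    flanking = (plan.left[:, None] == cof_indices[None, :]) | (
        plan.right[:, None] == cof_indices[None, :]
    )
    return ~((same & near) | flanking)


def scan_lod_matrix(
    X: np.ndarray,
    genotypes: np.ndarray,
    y: np.ndarray,
    plan: ScanPlan,
    cofactors: CofactorSet,
    settings: ScanSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """LOD at every grid position; fast path shared by all scans.

    ``X`` is the precomputed predictor matrix (``plan.predictors``) aligned
    with ``genotypes`` rows.  Positions are grouped by identical active
    covariate sets; within a group the trait and predictors are projected on
    the covariate basis once and each position costs a rank-one residual
    update.  Returns (lod, n_covariates_used).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    cof_idx = np.asarray(cofactors.head(settings.n_cofactors).indices, dtype=int)
    active = _active_cofactor_masks(plan, cof_idx, settings)
    lod = np.zeros(plan.n_positions)
    ncov = active.sum(axis=1).astype(int)
    # group positions sharing a covariate set
    if active.shape[1] == 0:
        keys = np.zeros(plan.n_positions, dtype=np.int64)
    else:
        keys = active @ (1 << np.arange(active.shape[1], dtype=np.int64))
    for key in np.unique(keys):
        idx = np.nonzero(keys == key)[0]
        mask = active[idx[0]]
        C = np.concatenate([np.ones((n, 1)), np.asarray(genotypes, dtype=float)[:, cof_idx[mask]]], axis=1)
        U = _orthonormal_basis(C)
        y_res = y - U @ (U.T @ y)
        rss0 = float(y_res @ y_res)
        Xg = X[:, idx]
        X_res = Xg - U @ (U.T @ Xg)
        den = np.einsum("ij,ij->j", X_res, X_res)
        num = (X_res.T @ y_res) ** 2
        ok = den > _RANK_TOL * n
        rss1 = np.where(ok, rss0 - np.divide(num, den, out=np.zeros_like(den), where=ok), rss0)
        if rss0 <= 0.0:
            lod[idx] = 0.0
            continue
        with np.errstate(divide="ignore"):
            vals = (n / 2.0) * np.log10(rss0 / np.maximum(rss1, 0.0))
        vals = np.where(rss1 <= 0.0, LOD_CAP, np.minimum(vals, LOD_CAP))
        lod[idx] = np.maximum(vals, 0.0)
    return lod, ncov


def stepwise_cofactors(dataset: SimulatedDataset, settings: ScanSettings | None = None) -> CofactorSet:
    """Forward/backward stepwise selection of background markers.

    Forward steps add the marker with the smallest partial-F p-value when it
    is below ``p_entry`` (ties broken by leftmost genome position); after
    each addition, backward elimination removes any included marker whose
    partial-F p-value exceeds ``p_entry``, repeating until stable.  Stops
    when no candidate qualifies or after ``max_forward_steps`` additions.
    The returned set is in entry order.
    """
    settings = settings or ScanSettings()
    loci = dataset.map.marker_table()
    order = _stepwise_indices(
        dataset.genotypes.values,
        dataset.trait.values,
        np.array([m.chromosome_id for m in loci]),
        np.array([m.position for m in loci]),
        settings,
    )
    return CofactorSet(tuple(loci[i] for i in order), tuple(order))


def _f_sf(F: float, df: int) -> float:
    """Upper tail of F(1, df); direct special-function call (hot path)."""
    if not np.isfinite(F):
        return 0.0
    return float(special.fdtrc(1.0, df, max(F, 0.0)))


def _stepwise_indices(
    G: np.ndarray,
    y: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    settings: ScanSettings,
) -> list[int]:
    """Entry-ordered stepwise selection on raw arrays.

    Candidates are kept residualized against the current model by rank-one
    Gram-Schmidt updates; for a fixed residual df the partial-F p-value is
    monotone in F, so each step ranks candidates by F and evaluates a
    single tail probability for the winner.  A backward pass after every
    addition triggers a from-scratch re-residualization only when it
    actually removes a marker.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if m < 2:
        raise ValueError("stepwise selection needs at least 2 markers")
    # precedence for tie-breaking: genome order
    rank = np.lexsort((pos, chrom))
    precedence = np.empty(m, dtype=int)
    precedence[rank] = np.arange(m)

    def residualize(active: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        U = _orthonormal_basis(np.concatenate([np.ones((n, 1)), G[:, active]], axis=1))
        y_res = y - U @ (U.T @ y)
        G_res = G - U @ (U.T @ G)
        usable = np.ones(m, dtype=bool)
        usable[active] = False
        return y_res, G_res, usable

    active: list[int] = []
    y_res, G_res, usable = residualize(active)
    forward_steps = 0
    while forward_steps < settings.max_forward_steps:
        df = n - len(active) - 2
        if df < 2:
            break
        rss = float(y_res @ y_res)
        if rss <= _RANK_TOL:
            break
        den = np.einsum("ij,ij->j", G_res, G_res)
        ok = usable & (den > _RANK_TOL * n)
        if not ok.any():
            break
        red = np.where(ok, (G_res.T @ y_res) ** 2 / np.where(ok, den, 1.0), -np.inf)
        resid = np.maximum(rss - red, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(resid > 0, red * df / resid, np.inf)
        F[~ok] = -np.inf
        # largest F wins; ties broken by leftmost genome position
        best = int(np.lexsort((precedence, -F))[0])
        if _f_sf(float(F[best]), df) >= settings.p_entry:
            break
        active.append(best)
        forward_steps += 1
        # rank-one Gram-Schmidt update of the residual pool
        u = G_res[:, best] / math.sqrt(den[best])
        y_res = y_res - u * float(u @ y_res)
        G_res = G_res - np.outer(u, u @ G_res)
        usable[best] = False
        if _backward_eliminate(G, y, active, settings):
            y_res, G_res, usable = residualize(active)
    return active


def _backward_eliminate(
    G: np.ndarray, y: np.ndarray, active: list[int], settings: ScanSettings
) -> bool:
    """Drop included markers whose partial-F p-value exceeds p_entry (in place).

    Returns True if any marker was removed.
    """
    n = G.shape[0]
    removed = False
    while len(active) > 0:
        X = np.concatenate([np.ones((n, 1)), G[:, active]], axis=1)
        df = n - X.shape[1]
        if df < 1:
            active.pop()
            removed = True
            continue
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            active.pop()
            removed = True
            continue
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / df
        if sigma2 <= 0:
            return removed
        # partial F of each included marker = squared t statistic
        var = sigma2 * np.diag(XtX_inv)[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(var > 0, beta[1:] ** 2 / var, np.inf)
        worst = int(np.argmin(F))  # smallest F = largest p at common df
        if _f_sf(float(F[worst]), df) > settings.p_entry:
            del active[worst]
            removed = True
        else:
            return removed
    return removed


def cim_scan(
    dataset: SimulatedDataset,
    cofactors: CofactorSet | None = None,
    settings: ScanSettings | None = None,
    plan: ScanPlan | None = None,
) -> list[LODCurve]:
    """Composite interval mapping scan; one LOD curve per chromosome.

    With an empty cofactor set this reduces to standard interval mapping
    (SIM).  ``plan`` may be supplied to amortize grid construction across
    scans of the same map.
    """
    settings = settings or ScanSettings()
    if cofactors is None:
        cofactors = CofactorSet((), ())
    if plan is None:
        plan = build_scan_plan(dataset.map, settings.walk)
    G = dataset.genotypes.values
    X = plan.predictors(G)
    lod, ncov = scan_lod_matrix(X, G, dataset.trait.values, plan, cofactors, settings)
    return [
        LODCurve(cid, plan.position[a:b], lod[a:b], ncov[a:b])
        for cid, a, b in plan.chrom_slices
    ]
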