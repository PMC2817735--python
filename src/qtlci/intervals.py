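"""Positional confidence intervals for QTL located by CIM.

Three procedures are provided:

``SI``
    LOD support interval: follow the LOD curve from its peak down by a
    prescribed drop (2.0 by default) on each side.
``NPCI``
    Naive bootstrap percentile interval: resample individuals with
    replacement, rescan each replicate *reusing the cofactor set selected on
    the original data*, and take central percentiles of the per-chromosome
    peak positions.
``CIM-NPCI``
    Bootstrap percentile interval with the complete CIM analysis — stepwise
    cofactor re-selection included — repeated on every replicate, so the
    interval reflects the procedural variability of CIM itself.

Significance is assessed against a permutation threshold (genome-wide
maximum LOD under trait shuffling); the *selective* variants keep only
bootstrap peaks exceeding the original dataset's threshold before taking
percentiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from qtlci.cim import (
    CofactorSet,
    LODCurve,
    ScanPlan,
    ScanSettings,
    _stepwise_indices,
    build_scan_plan,
    scan_lod_matrix,
)
from qtlci.genmap import MarkerLocus
from qtlci.popsim import SimulatedDataset

__all__ = [
    "ConfidenceInterval",
    "PeakRecord",
    "ThresholdResult",
    "NoSignificantPeaksError",
    "support_interval",
    "permutation_threshold",
    "bootstrap_peaks",
    "selective_filter",
    "percentile_interval",
    "cim_npci",
]

#: fraction of B below which selective filtering falls back to non-selective
SELECTIVE_FALLBACK_FRACTION = 0.2


class NoSignificantPeaksError(RuntimeError):
    """Selective filtering removed every bootstrap peak."""


@dataclass(frozen=True)
class PeakRecord:
    """Per-chromosome LOD maximum of one scan."""

    chromosome_id: int
    position: float
    height: float


@dataclass(frozen=True)
class ThresholdResult:
    """Permutation significance threshold for the genome-wide maximum LOD."""

    threshold: float
    P: int
    alpha: float
    null_max_lods: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "null_max_lods", np.asarray(self.null_max_lods, dtype=float))


@dataclass(frozen=True)
class ConfidenceInterval:
    """A positional CI on one chromosome, tagged with its method of origin.

    ``selective_fallback`` marks bootstrap intervals where too few peaks
    survived the selective filter and the non-selective interval was
    reported instead.
    """

    chromosome_id: int
    lower: float
    upper: float
    method: str  # "SI" | "NPCI" | "CIM-NPCI"
    selective: bool = False
    peak: float = math.nan
    n_replicates_used: int = 0
    selective_fallback: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} > upper {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, position: float) -> bool:
        """Inclusive containment of a cM position."""
        return self.lower <= position <= self.upper


def support_interval(curve: LODCurve, drop: float = 2.0) -> ConfidenceInterval:
    """LOD support interval: positions connected to the peak with LOD within ``drop``.

    The peak is the leftmost argmax; the interval extends from the peak in
    both directions while the curve stays at or above ``peak - drop``, and
    is truncated at the chromosome ends.  Endpoints are reported on the scan
    grid (no sub-grid interpolation).
    """
    lod = curve.lod
    i_peak = int(np.argmax(lod))
    thresh = lod[i_peak] - drop
    lo = i_peak
    while lo > 0 and lod[lo - 1] >= thresh:
        lo -= 1
    hi = i_peak
    while hi < len(lod) - 1 and lod[hi + 1] >= thresh:
        hi += 1
    return ConfidenceInterval(
        curve.chromosome_id,
        float(curve.grid[lo]),
        float(curve.grid[hi]),
        method="SI",
        peak=float(curve.grid[i_peak]),
    )


def _curve_peaks(plan: ScanPlan, lod: np.ndarray) -> list[PeakRecord]:
    peaks = []
    for cid, a, b in plan.chrom_slices:
        i = int(np.argmax(lod[a:b]))
        peaks.append(PeakRecord(cid, float(plan.position[a + i]), float(lod[a + i])))
    return peaks


def _scan_peaks(
    X: np.ndarray,
    G: np.ndarray,
    y: np.ndarray,
    plan: ScanPlan,
    cofactors: CofactorSet,
    settings: ScanSettings,
) -> list[PeakRecord]:
    lod, _ = scan_lod_matrix(X, G, y, plan, cofactors, settings)
    return _curve_peaks(plan, lod)


def _reselect(G: np.ndarray, y: np.ndarray, plan: ScanPlan, settings: ScanSettings) -> CofactorSet:
    """Stepwise cofactor selection on raw arrays (bootstrap fast path)."""
    order = _stepwise_indices(G, y, plan.marker_chrom, plan.marker_pos, settings)
    markers = tuple(
        MarkerLocus(int(plan.marker_chrom[i]), f"m{i + 1}", float(plan.marker_pos[i]))
        for i in order
    )
    return CofactorSet(markers, tuple(order))


def permutation_threshold(
    dataset: SimulatedDataset,
    P: int,
    alpha: float,
    settings: ScanSettings | None = None,
    rng: np.random.Generator | None = None,
    reselect: bool = True,
    cofactors: CofactorSet | None = None,
    plan: ScanPlan | None = None,
) -> ThresholdResult:
    """Permutation threshold for the genome-wide maximum LOD.

    The trait is shuffled against the genotypes ``P`` times; each permuted
    dataset is analyzed by CIM (with cofactor re-selection by default, or
    with a frozen ``cofactors`` set when ``reselect=False``) and the
    genome-wide maximum LOD recorded.  The threshold is the
    ``ceil(P*(1-alpha))``-th order statistic of the null maxima.
    """
    settings = settings or ScanSettings()
    rng = rng or np.random.default_rng()
    if P * alpha < 1:
        raise ValueError(f"P*alpha = {P * alpha} < 1: empirical quantile undefined")
    if not reselect and cofactors is None:
        raise ValueError("reselect=False requires a frozen cofactor set")
    if plan is None:
        plan = build_scan_plan(dataset.map, settings.walk)
    G = dataset.genotypes.values
    X = plan.predictors(G)
    y = dataset.trait.values
    if np.ptp(y) == 0:
        warnings.warn("constant trait: permutation threshold is degenerate")
    maxima = np.empty(P)
    for b in range(P):
        y_perm = y[rng.permutation(y.shape[0])]
        cof = _reselect(G, y_perm, plan, settings) if reselect else cofactors
        lod, _ = scan_lod_matrix(X, G, y_perm, plan, cof, settings)
        maxima[b] = lod.max()
    k = math.ceil(P * (1.0 - alpha))
    threshold = float(np.sort(maxima)[k - 1])
    return ThresholdResult(threshold, P, alpha, maxima)


def bootstrap_peaks(
    dataset: SimulatedDataset,
    B: int,
    reselect: bool,
    settings: ScanSettings | None = None,
    rng: np.random.Generator | None = None,
    cofactors: CofactorSet | None = None,
    plan: ScanPlan | None = None,
    return_cofactors: bool = False,
):
    """Per-chromosome LOD peaks of ``B`` bootstrap replicates.

    Each replicate resamples the ``n`` individuals with replacement (trait
    values stay paired with their genotypes).  With ``reselect=True`` the
    stepwise cofactor selection is redone on every replicate (CIM-NPCI);
    with ``reselect=False`` the supplied original ``cofactors`` are reused
    (NPCI).  Returns a list over chromosomes of lists of
    :class:`PeakRecord`; degenerate replicates (constant trait) are skipped
    with a warning, so the lists may be shorter than ``B``.
    """
    settings = settings or ScanSettings()
    rng = rng or np.random.default_rng()
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if not reselect and cofactors is None:
        raise ValueError("reselect=False requires the original cofactor set")
    if plan is None:
        plan = build_scan_plan(dataset.map, settings.walk)
    G = dataset.genotypes.values
    X = plan.predictors(G)
    y = dataset.trait.values
    n = y.shape[0]
    out: list[list[PeakRecord]] = [[] for _ in plan.chrom_slices]
    cof_sets: list[CofactorSet] = []
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        y_b = y[rows]
        if np.ptp(y_b) == 0:
            warnings.warn(f"bootstrap replicate {b} has a constant trait; skipped")
            continue
        G_b = G[rows]
        X_b = X[rows]
        cof = _reselect(G_b, y_b, plan, settings) if reselect else cofactors
        cof_sets.append(cof)
        for ci, rec in enumerate(_scan_peaks(X_b, G_b, y_b, plan, cof, settings)):
            out[ci].append(rec)
    if return_cofactors:
        return out, cof_sets
    return out


def selective_filter(peaks: list[PeakRecord], threshold: float) -> list[PeakRecord]:
    """Keep peaks whose height strictly exceeds ``threshold`` (order preserved)."""
    kept = [p for p in peaks if p.height > threshold]
    if not kept:
        raise NoSignificantPeaksError(
            f"no bootstrap peaks exceed the threshold {threshold}"
        )
    return kept


def percentile_interval(positions, alpha: float = 0.05) -> tuple[float, float]:
    """Central ``1 - alpha`` percentile interval by order statistics.

    With ``B`` sorted positions the bounds are the ``ceil(B*alpha/2)``-th
    and ``ceil(B*(1-alpha/2))``-th order statistics (1-indexed).
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    B = pos.shape[0]
    if B < 2:
        raise ValueError(f"need >= 2 positions, got {B}")
    lo = max(math.ceil(B * alpha / 2.0), 1)
    hi = min(math.ceil(B * (1.0 - alpha / 2.0)), B)
    return float(pos[lo - 1]), float(pos[hi - 1])


def _bootstrap_interval(
    chrom_peaks: list[PeakRecord],
    threshold: float,
    alpha: float,
    selective: bool,
    method: str,
    original_peak: float,
) -> ConfidenceInterval:
    """Percentile interval from one chromosome's bootstrap peaks."""
    B = len(chrom_peaks)
    fallback = False
    records = chrom_peaks
    if selective:
        kept = [p for p in chrom_peaks if p.height > threshold]
        if len(kept) < SELECTIVE_FALLBACK_FRACTION * B:
            warnings.warn(
                f"chromosome {chrom_peaks[0].chromosome_id}: only {len(kept)}/{B} bootstrap "
                "peaks exceed the threshold; reporting the non-selective interval"
            )
            fallback = True
        else:
            records = kept
    lower, upper = percentile_interval([p.position for p in records], alpha)
    return ConfidenceInterval(
        chrom_peaks[0].chromosome_id,
        lower,
        upper,
        method=method,
        selective=selective and not fallback,
        peak=original_peak,
        n_replicates_used=len(records),
        selective_fallback=fallback,
    )


def cim_npci(
    dataset: SimulatedDataset,
    B: int = 1000,
    P: int = 1000,
    alpha: float = 0.05,
    selective: bool = True,
    settings: ScanSettings | None = None,
    rng: np.random.Generator | None = None,
    reselect: bool = True,
) -> tuple[list[ConfidenceInterval], ThresholdResult]:
    """Bootstrap percentile CIs for every chromosome with a significant peak.

    Pipeline: permutation threshold on the original data; ``B`` bootstrap
    replicates with (``reselect=True``, the CIM-NPCI method) or without
    (``reselect=False``, NPCI) per-replicate cofactor re-selection;
    optional selective filtering of sub-threshold peaks; percentile
    interval of the surviving peak positions.  Chromosomes whose
    original-data peak does not exceed the threshold yield no interval.
    """
    settings = settings or ScanSettings()
    rng = rng or np.random.default_rng()
    plan = build_scan_plan(dataset.map, settings.walk)
    G = dataset.genotypes.values
    X = plan.predictors(G)
    y = dataset.trait.values

    original_cof = _reselect(G, y, plan, settings)
    lod, _ = scan_lod_matrix(X, G, y, plan, original_cof, settings)
    original_peaks = _curve_peaks(plan, lod)

    thr = permutation_threshold(
        dataset, P, alpha, settings, rng, reselect=True, plan=plan
    )
    peaks = bootstrap_peaks(
        dataset, B, reselect, settings, rng,
        cofactors=None if reselect else original_cof, plan=plan,
    )
    method = "CIM-NPCI" if reselect else "NPCI"
    intervals = []
    for ci, orig in enumerate(original_peaks):
        if orig.height <= thr.threshold:
            continue
        intervals.append(
            _bootstrap_interval(peaks[ci], thr.threshold, alpha, selective, method, orig.position)
        )
    return intervals, thr
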