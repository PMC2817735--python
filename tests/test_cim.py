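import itertools

import numpy as np
import pytest
from scipy import special

from conftest import brute_force_lod
from qtlci.cim import (
    LOD_CAP,
    CofactorSet,
    ScanSettings,
    _active_cofactor_masks,
    build_scan_plan,
    cim_scan,
    conditional_expectation,
    regression_lod,
    stepwise_cofactors,
)
from qtlci.genmap import (
    ChromosomeMap,
    GeneticMap,
    MarkerLocus,
    haldane_recomb,
    place_qtls,
    ril_expand,
)
from qtlci.popsim import dataset_rng, make_dataset


class TestRegressionLOD:
    def test_matches_brute_force_ols(self):
        """(n/2)*log10(RSS0/RSS1) against an independent lstsq fit."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = 50
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            cov = rng.normal(size=(n, 2))
            assert regression_lod(y, x, cov) == pytest.approx(
                max(brute_force_lod(y, x, cov), 0.0), abs=1e-10
            )
            assert regression_lod(y, x) == pytest.approx(
                max(brute_force_lod(y, x), 0.0), abs=1e-10
            )

    def test_perfect_fit_is_capped(self):
        y = np.arange(30.0)
        assert regression_lod(y, y) == LOD_CAP

    def test_null_lod_median_matches_chi_square(self):
        """Under the null, 2*ln(10)*LOD ~ chi2(1); the median LOD is ~0.0988."""
        rng = np.random.default_rng(1)
        n = 2000
        lods = [
            regression_lod(rng.normal(size=n), rng.normal(size=n)) for _ in range(600)
        ]
        assert np.median(lods) == pytest.approx(0.4549 / (2 * np.log(10)), abs=0.03)

    def test_constant_predictor_scores_zero(self):
        rng = np.random.default_rng(2)
        assert regression_lod(rng.normal(size=40), np.ones(40)) == 0.0

    def test_collinear_covariates_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        y, x = rng.normal(size=60), rng.normal(size=60)
        c = rng.normal(size=60)
        with pytest.warns(UserWarning, match="rank-deficient"):
            lod = regression_lod(y, x, np.column_stack([c, c]))
        assert lod == pytest.approx(max(brute_force_lod(y, x, c), 0.0), abs=1e-8)


def enumerate_conditional(mL, mR, dL, dR):
    """Brute-force enumeration of the two-interval Markov chain over QTL states."""
    r1 = ril_expand(haldane_recomb(dL))
    r2 = ril_expand(haldane_recomb(dR))
    num = {+1: 0.0, -1: 0.0}
    for q in (+1, -1):
        p = 0.5  # P(mL)
        p *= (1 - r1) if q == mL else r1
        p *= (1 - r2) if mR == q else r2
        num[q] += p
    z = num[+1] + num[-1]
    return (num[+1] - num[-1]) / z


class TestConditionalExpectation:
    def test_coincident_marker_returns_marker_code(self):
        assert conditional_expectation(+1, -1, 0.0, 7.0) == 1.0
        assert conditional_expectation(-1, +1, 5.0, 0.0) == 1.0

    def test_midpoint_with_discordant_markers_is_zero(self):
        assert conditional_expectation(+1, -1, 8.0, 8.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("dL,dR", [(10.0, 10.0), (1.0, 14.0), (3.0, 17.0), (0.5, 0.5)])
    @pytest.mark.parametrize("mL,mR", list(itertools.product([+1, -1], repeat=2)))
    def test_matches_markov_chain_enumeration(self, mL, mR, dL, dR):
        assert conditional_expectation(mL, mR, dL, dR) == pytest.approx(
            enumerate_conditional(mL, mR, dL, dR), abs=1e-12
        )

    def test_impossible_configuration_raises(self):
        with pytest.raises(ValueError, match="coincident"):
            conditional_expectation(+1, -1, 0.0, 0.0)

    def test_expectation_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            dL, dR = rng.uniform(0.1, 30, size=2)
            e = conditional_expectation(+1, +1, dL, dR)
            assert -1.0 <= e <= 1.0


def brute_stepwise(G, y, chrom, pos, p_entry=0.05, max_steps=10):
    """Exhaustive oracle: recompute every partial F at every step via lstsq."""
    n, m = G.shape
    order = np.lexsort((pos, chrom))
    prec = np.empty(m, int)
    prec[order] = np.arange(m)
    active = []
    steps = 0
    while steps < max_steps:
        df = n - len(active) - 2
        best, bestF = None, -np.inf
        for j in range(m):
            if j in active:
                continue
            X0 = np.column_stack([np.ones(n)] + [G[:, a] for a in active])
            X1 = np.column_stack([X0, G[:, j]])
            r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
            r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
            rss0, rss1 = r0 @ r0, r1 @ r1
            F = np.inf if rss1 < 1e-12 else (rss0 - rss1) / (rss1 / df)
            if F > bestF + 1e-9 or (
                abs(F - bestF) <= 1e-9 and best is not None and prec[j] < prec[best]
            ):
                best, bestF = j, F
        if float(special.fdtrc(1, df, bestF)) >= p_entry:
            break
        active.append(best)
        steps += 1
        changed = True
        while changed and active:
            changed = False
            X = np.column_stack([np.ones(n)] + [G[:, a] for a in active])
            dfb = n - X.shape[1]
            XtXi = np.linalg.inv(X.T @ X)
            b = XtXi @ (X.T @ y)
            r = y - X @ b
            s2 = (r @ r) / dfb
            Fs = b[1:] ** 2 / (s2 * np.diag(XtXi)[1:])
            w = int(np.argmin(Fs))
            if float(special.fdtrc(1, dfb, Fs[w])) > p_entry:
                del active[w]
                changed = True
    return active


class TestStepwiseCofactors:
    def test_dominant_marker_enters_first(self, tiny_one_qtl):
        cof = stepwise_cofactors(tiny_one_qtl)
        first = cof.markers[0]
        assert (first.chromosome_id, first.position) == (1, 10.0)

    def test_null_trait_selection_is_small_and_significant(self, tiny_null, settings):
        cof = stepwise_cofactors(tiny_null, settings)
        assert len(cof) <= settings.max_forward_steps
        # every retained marker passes the stay criterion in the final model
        if len(cof):
            G = tiny_null.genotypes.values
            y = tiny_null.trait.values
            n = len(y)
            X = np.column_stack([np.ones(n)] + [G[:, i] for i in cof.indices])
            XtXi = np.linalg.inv(X.T @ X)
            b = XtXi @ (X.T @ y)
            r = y - X @ b
            s2 = (r @ r) / (n - X.shape[1])
            Fs = b[1:] ** 2 / (s2 * np.diag(XtXi)[1:])
            ps = special.fdtrc(1, n - X.shape[1], Fs)
            assert np.all(ps <= settings.p_entry)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_selection_path_matches_enumeration_oracle(self, seed):
        """Identical entry/removal path to an oracle recomputing every partial F."""
        rng = np.random.default_rng(seed)
        n, m = 80, 9
        chrom = np.array([1] * 5 + [2] * 4)
        pos = np.array([0.0, 10, 20, 30, 40, 0, 15, 30, 45])
        G = rng.choice([-1.0, 1.0], size=(n, m))
        y = 0.7 * G[:, 2] + 0.5 * G[:, 6] + rng.normal(size=n)
        markers = tuple(MarkerLocus(int(c), f"m{i}", float(p)) for i, (c, p) in enumerate(zip(chrom, pos)))
        chroms = (
            ChromosomeMap(1, 40.0, markers[:5]),
            ChromosomeMap(2, 45.0, markers[5:]),
        )
        from qtlci.popsim import GenotypeMatrix, SimulatedDataset, TraitVector

        ds = SimulatedDataset(GeneticMap(chroms), GenotypeMatrix(G, markers), TraitVector(y))
        assert list(stepwise_cofactors(ds).indices) == brute_stepwise(G, y, chrom, pos)


class TestCIMScan:
    def test_166_grid_points_per_chromosome(self, benchmark_dataset, settings):
        curves = cim_scan(benchmark_dataset, settings=settings)
        assert len(curves) == 4
        for c in curves:
            assert len(c.grid) == 166
            assert c.grid[0] == 0.0 and c.grid[-1] == 165.0
            assert np.all(np.diff(c.grid) == 1.0)
            assert np.all(c.lod >= 0)

    def test_sim_equivalence_at_marker_positions(self, benchmark_dataset):
        """With no cofactors, marker-position LODs equal single-marker OLS LODs."""
        curves = cim_scan(benchmark_dataset, CofactorSet((), ()))
        y = benchmark_dataset.trait.values
        G = benchmark_dataset.genotypes.values
        loci = benchmark_dataset.map.marker_table()
        by_chrom = {c.chromosome_id: c for c in curves}
        for j, m in enumerate(loci):
            curve = by_chrom[m.chromosome_id]
            i = int(np.where(curve.grid == m.position)[0][0])
            expected = max(brute_force_lod(y, G[:, j]), 0.0)
            assert curve.lod[i] == pytest.approx(expected, abs=1e-8)

    def test_cim_matches_per_position_ols_oracle(self, benchmark_dataset, settings, bplan):
        """Grouped rank-one scan equals position-by-position OLS with the
        same covariate-blocking rules."""
        cof = stepwise_cofactors(benchmark_dataset, settings)
        curves = cim_scan(benchmark_dataset, cof, settings, plan=bplan)
        G = benchmark_dataset.genotypes.values
        y = benchmark_dataset.trait.values
        X = bplan.predictors(G)
        idx = np.asarray(cof.head(settings.n_cofactors).indices, dtype=int)
        active = _active_cofactor_masks(bplan, idx, settings)
        rng = np.random.default_rng(0)
        flat = np.concatenate([c.lod for c in curves])
        for i in rng.choice(bplan.n_positions, size=40, replace=False):
            cov = G[:, idx[active[i]]]
            expected = max(brute_force_lod(y, X[:, i], cov), 0.0)
            assert flat[i] == pytest.approx(expected, abs=1e-8)

    def test_window_blocks_nearby_same_chromosome_cofactor(self, bplan, settings):
        """A cofactor at 20 cM is excluded at test position 15 (|d|=5 <= 10)."""
        cof_idx = np.array([10])  # chromosome 1, 20 cM in the benchmark map
        assert bplan.marker_pos[10] == 20.0 and bplan.marker_chrom[10] == 1
        active = _active_cofactor_masks(bplan, cof_idx, settings)
        i15 = int(np.where((bplan.chrom_id == 1) & (bplan.position == 15.0))[0][0])
        i31 = int(np.where((bplan.chrom_id == 1) & (bplan.position == 31.0))[0][0])
        i30 = int(np.where((bplan.chrom_id == 1) & (bplan.position == 30.0))[0][0])
        other = int(np.where(bplan.chrom_id == 2)[0][0])
        assert not active[i15, 0]          # inside the window
        assert not active[i30, 0]          # boundary (= window) is blocked
        assert active[i31, 0]              # just outside
        assert active[other, 0]            # other chromosomes never blocked

    def test_flanking_markers_never_serve_as_covariates(self, bplan, settings):
        """The markers spanning the test position are excluded at any distance."""
        cof_idx = np.array([11])  # chromosome 1, 23 cM
        active = _active_cofactor_masks(bplan, cof_idx, settings)
        i = int(np.where((bplan.chrom_id == 1) & (bplan.position == 24.0))[0][0])
        assert bplan.left[i] == 11
        assert not active[i, 0]

    def test_lod_invariant_to_affine_trait_rescaling(self, tiny_one_qtl, settings):
        from qtlci.popsim import SimulatedDataset, TraitVector

        cof = stepwise_cofactors(tiny_one_qtl, settings)
        base = cim_scan(tiny_one_qtl, cof, settings)
        rescaled = SimulatedDataset(
            tiny_one_qtl.map,
            tiny_one_qtl.genotypes,
            TraitVector(3.7 * tiny_one_qtl.trait.values - 11.0),
            tiny_one_qtl.truth,
        )
        for c0, c1 in zip(base, cim_scan(rescaled, cof, settings)):
            np.testing.assert_allclose(c0.lod, c1.lod, atol=1e-8)

    def test_peak_localizes_strong_single_qtl(self, bmap, settings, bplan):
        """argmax within 2 cM of a strong QTL (a=3, h2=0.9) in >=95% of scans."""
        from qtlci.genmap import QTLPlacement

        hits = 0
        n_sim = 100
        for i in range(n_sim):
            ds = make_dataset(bmap, [QTLPlacement(1, 43.0, 3.0)], 200, 0.9, dataset_rng(55, i))
            cof = stepwise_cofactors(ds, settings)
            curve = cim_scan(ds, cof, settings, plan=bplan)[0]
            hits += abs(curve.peak()[0] - 43.0) <= 2.0
        assert hits / n_sim >= 0.95

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ScanSettings(walk=0.0)
        with pytest.raises(ValueError):
            ScanSettings(window=-1.0)
        with pytest.raises(ValueError):
            ScanSettings(p_entry=1.5)
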