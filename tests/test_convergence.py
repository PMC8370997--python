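"""Coancestry constructors, composite likelihood, and case classification."""

import numpy as np
import pytest

from paradapt.convergence import (
    ConvergenceModel,
    ScenarioParams,
    classify_case,
    neutral_coancestry,
    scenario_coancestry,
    summarize_sources,
    sweep_retention,
)
from paradapt.genotypes import AlleleFreqTable
from paradapt.scan import GeneModel
from paradapt.simulate import simulate_mvn_freqs

import pandas as pd


def sel_params(scenario, **kw):
    kw.setdefault("selected", (0, 2))
    kw.setdefault("Ne", 30000.0)
    return ScenarioParams(scenario, **kw)


class TestSweepRetention:
    def test_zero_distance_full_retention(self):
        assert sweep_retention(0.0, sel_params("ind", s=0.05)) == 1.0

    def test_far_distance_vanishes(self):
        y = sweep_retention(1e12, sel_params("ind", s=0.05, r_bp=1e-8))
        assert y < 1e-12

    def test_hand_value(self):
        # tau = log(120000*0.05)/0.05 = 173.97; y = exp(-1e-8*1e4*tau)
        p = sel_params("ind", s=0.05, r_bp=1e-8, Ne=30000, ploidy=4)
        assert sweep_retention(1e4, p) == pytest.approx(0.98274, abs=2e-5)

    def test_invalid_sweep_regime_errors(self):
        with pytest.raises(ValueError, match="A\\*s"):
            ScenarioParams("ind", s=1e-7, selected=(0, 2), Ne=30000.0)


class TestScenarioCoancestry:
    def test_neutral_returns_f0(self, quartet_F0):
        out = scenario_coancestry(quartet_F0, 100.0, sel_params("neutral"))
        assert np.allclose(out, quartet_F0)

    def test_large_distance_neutral_limit(self, quartet_F0):
        for sc, kw in [("ind", {}), ("standing", {"g": 0.01, "t": 500.0}),
                       ("migration", {"m": 1e-3, "src": 0})]:
            p = sel_params(sc, s=0.05, r_bp=1e-8, **kw)
            out = scenario_coancestry(quartet_F0, 1e13, p)
            assert np.abs(out - quartet_F0).max() < 1e-8, sc

    def test_ind_leaves_offdiagonal_unchanged(self, quartet_F0):
        p = sel_params("ind", s=0.05)
        out = scenario_coancestry(quartet_F0, 0.0, p)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(out[off], quartet_F0[off])
        assert out[0, 0] > quartet_F0[0, 0]

    def test_standing_single_origin_limit(self, quartet_F0):
        # g -> 1/A (single copy) with a long standing window: coalescence
        # dominates and the cross-population selected entry approaches
        # y^2 + (1 - y^2) F0_ij
        A = 120000.0
        p = sel_params("standing", s=0.05, g=1.5 / A, t=1e4, r_bp=1e-10)
        d = 100.0
        y = sweep_retention(d, p)
        out = scenario_coancestry(quartet_F0, d, p)
        expected = y**2 + (1 - y**2) * quartet_F0[0, 2]
        assert out[0, 2] == pytest.approx(expected, abs=1e-3)

    def test_standing_raises_cross_pop_ind_does_not(self, quartet_F0):
        d = 10.0
        st = scenario_coancestry(
            quartet_F0, d, sel_params("standing", s=0.05, g=0.001, t=1000.0)
        )
        ind = scenario_coancestry(quartet_F0, d, sel_params("ind", s=0.05))
        assert st[0, 2] > quartet_F0[0, 2] + 0.1
        assert ind[0, 2] == pytest.approx(quartet_F0[0, 2])

    def test_all_grid_matrices_psd(self, quartet_F0):
        from paradapt.convergence import default_grids
        import itertools

        g = default_grids()
        d = np.array([0.0, 100.0, 1000.0, 25000.0])
        a = 32.0
        for s, gg, t in itertools.product(g["s"], g["g"], g["t"]):
            if 120000 * s <= 1:
                continue
            p = sel_params("standing", s=s, g=gg, t=t)
            out = scenario_coancestry(quartet_F0, d, p)
            C = out.copy()
            idx = np.arange(4)
            C[:, idx, idx] += (1 - C[:, idx, idx]) / a
            w = np.linalg.eigvalsh(C)
            assert w.min() >= -1e-8

    def test_migration_needs_src(self, quartet_F0):
        with pytest.raises(ValueError, match="src"):
            scenario_coancestry(
                quartet_F0, 10.0,
                ScenarioParams("migration", s=0.05, m=1e-3, selected=(0, 2),
                               Ne=30000.0),
            )


class TestCompositeLikelihood:
    def _model(self, quartet_F0, seed=0, scenario=None):
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(np.arange(1, 52001), 120, replace=False))
        gene = GeneModel("g", "chr1", 24000, 28000)
        copies = np.array([32] * 4)
        params = scenario or sel_params("neutral")
        x = simulate_mvn_freqs(quartet_F0, params, 120, positions, 26000.0,
                               copies, seed)
        return ConvergenceModel(x, positions, copies, gene, quartet_F0)

    def test_neutral_profile_flat(self, quartet_F0):
        m = self._model(quartet_F0)
        fit = m._fit_scenario("neutral", (0, 2), None)
        assert fit.profile["loglik"].nunique() == 1

    def test_snp_permutation_invariance(self, quartet_F0):
        m = self._model(quartet_F0)
        F = np.broadcast_to(quartet_F0, (len(m.positions), 4, 4)).copy()
        base = m._loglik_given_F(F)
        perm = np.random.default_rng(1).permutation(len(m.positions))
        m2 = ConvergenceModel(
            m.freqs[perm], m.positions[perm], m.copies, m.gene, quartet_F0
        )
        assert m2._loglik_given_F(F[perm]) == pytest.approx(base)

    def test_mcl_nondecreasing_under_grid_refinement(self, quartet_F0):
        m = self._model(quartet_F0, seed=3)
        coarse = {"s": [0.05], "g": [0.01], "t": [500.0], "m": [1e-3]}
        fine = {"s": [0.01, 0.05, 0.1], "g": [0.001, 0.01], "t": [500.0, 1000.0],
                "m": [1e-3, 1e-2]}
        f_c = m._fit_scenario("standing", (0, 2), coarse)
        f_f = m._fit_scenario("standing", (0, 2), fine)
        assert f_f.mcl >= f_c.mcl - 1e-9

    def test_pair_relabelling_invariance(self, quartet_F0):
        params = sel_params("standing", s=0.05, g=0.001, t=500.0)
        m = self._model(quartet_F0, seed=5, scenario=params)
        r1 = m.fit()
        # swap the two pairs: columns (S2,N2,S1,N1)
        perm = [2, 3, 0, 1]
        F0p = quartet_F0[np.ix_(perm, perm)]
        m2 = ConvergenceModel(
            m.freqs[:, perm], m.positions, m.copies[perm], m.gene, F0p
        )
        r2 = m2.fit()
        assert r1.classification == r2.classification
        assert r1.delta_s == pytest.approx(r2.delta_s, rel=1e-6)

    def test_underpowered_flagged(self, quartet_F0):
        rng = np.random.default_rng(9)
        positions = np.array([25000, 26000, 27000])
        gene = GeneModel("g", "chr1", 24000, 28000)
        x = simulate_mvn_freqs(quartet_F0, sel_params("neutral"), 3, positions,
                               26000.0, np.array([32] * 4), 1)
        m = ConvergenceModel(x, positions, np.array([32] * 4), gene, quartet_F0)
        assert m.underpowered


class TestClassifyCase:
    def test_rule_arithmetic_ambiguous(self):
        assert classify_case(30.0, 29.0, "standing") == "ambiguous"

    def test_below_threshold_neutral(self):
        assert classify_case(20.9, 0.0, "standing") == "neutral"

    def test_clear_margin_returns_scenario(self):
        assert classify_case(100.0, 20.0, "ind") == "ind"

    def test_negative_delta_n_treated_as_zero(self):
        assert classify_case(22.0, -50.0, "migration") == "migration"


class TestNeutralCoancestry:
    def _af(self, x, a=32):
        n = x.shape[1]
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, n + 1), "ref": "A", "alt": "T"}
        )
        alt = np.round(x * a).astype(int)
        tot = np.full(x.shape, a)
        return AlleleFreqTable(["S1", "N1", "S2", "N2"], sites, alt, tot)

    def test_identical_populations_offdiag_matches_diag(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.9, 3000)
        x = np.tile(base, (4, 1))
        F = neutral_coancestry(self._af(x), ["S1", "N1", "S2", "N2"]).F
        # all populations identical: off-diagonal coancestry ~ diagonal
        assert abs(F[0, 1] - F[0, 0]) < 0.05 * max(F[0, 0], 0.02) + 0.02

    def test_independent_populations_near_zero_offdiag(self):
        rng = np.random.default_rng(1)
        eps = rng.uniform(0.2, 0.8, 5000)
        x = np.clip(eps + rng.normal(0, 0.05, (4, 5000)), 0, 1)
        F = neutral_coancestry(self._af(x), ["S1", "N1", "S2", "N2"]).F
        # mean-centering induces a small negative bias; just require that
        # no spurious positive coancestry appears
        assert F[0, 2] < 0.02

    def test_split_topology_ordering(self):
        # pairs share drift: within-pair coancestry above cross-pair
        rng = np.random.default_rng(2)
        eps = rng.uniform(0.2, 0.8, 4000)
        shared1 = rng.normal(0, 0.08, 4000)
        shared2 = rng.normal(0, 0.08, 4000)
        x = np.clip(
            np.stack([
                eps + shared1 + rng.normal(0, 0.04, 4000),
                eps + shared1 + rng.normal(0, 0.04, 4000),
                eps + shared2 + rng.normal(0, 0.04, 4000),
                eps + shared2 + rng.normal(0, 0.04, 4000),
            ]), 0, 1,
        )
        F = neutral_coancestry(self._af(x), ["S1", "N1", "S2", "N2"]).F
        assert F[0, 1] > F[0, 2] + 0.02
        assert F[2, 3] > F[1, 2] + 0.02

    def test_too_few_snps_errors(self):
        x = np.tile(np.array([[0.5, 0.4]]), (4, 1))
        with pytest.raises(ValueError, match="SNPs"):
            neutral_coancestry(self._af(x), ["S1", "N1", "S2", "N2"])


def test_summarize_sources_proportions(quartet_F0):
    class Fake:
        def __init__(self, c):
            self.classification_collapsed = c

    cases = [Fake("shared_origin")] * 28 + [Fake("de_novo")]
    out = summarize_sources(cases)
    shared = out[out["classification"] == "shared_origin"].iloc[0]
    assert shared["n_cases"] == 28
    assert shared["prop_of_non_neutral"] == pytest.approx(28 / 29)
    all_neutral = summarize_sources([Fake("neutral")] * 5)
    assert all_neutral[all_neutral["classification"] == "neutral"].iloc[0][
        "prop_of_all"
    ] == 1.0
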