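import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cecanova.errors import AlignmentError, ContrastError, ParameterError
from cecanova.perm_anova import (
    Contrast,
    bh_fdr,
    combined_factor,
    contrast_estimate,
    f_statistic,
    fit_cell_means,
    interaction_test,
    permutation_pvalue,
    run_differential_abundance,
    standard_contrasts,
)

CELL_A = ("A", 1, "with", "AL")
CELL_B = ("B", 5, "with", "AL")
TWO_CELLS = [CELL_A, CELL_A, CELL_B, CELL_B]
AB = Contrast("ab", {CELL_A: 1.0, CELL_B: -1.0})


class TestFitCellMeans:
    def test_hand_ols(self):
        fit = fit_cell_means(np.array([1.0, 3.0, 5.0, 7.0]), TWO_CELLS)
        assert np.allclose(sorted(fit.means), [2.0, 6.0])
        assert fit.resid_ms == pytest.approx(2.0)
        assert fit.resid_df == 2

    def test_constant_response(self):
        fit = fit_cell_means(np.full(4, 3.0), TWO_CELLS)
        assert np.allclose(fit.means, 3.0)
        assert fit.resid_ms == pytest.approx(0.0)

    def test_sample_order_invariance(self):
        y = np.array([1.0, 3.0, 5.0, 7.0])
        perm = [2, 0, 3, 1]
        fit1 = fit_cell_means(y, TWO_CELLS)
        fit2 = fit_cell_means(y[perm], [TWO_CELLS[i] for i in perm])
        assert np.allclose(fit1.means, fit2.means)
        assert fit1.resid_ms == pytest.approx(fit2.resid_ms)


class TestFStatistic:
    def test_equal_means_zero(self):
        fit = fit_cell_means(np.array([1.0, 3.0, 1.0, 3.0]), TWO_CELLS)
        assert f_statistic(fit, AB) == pytest.approx(0.0)

    def test_equals_squared_t(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.normal(size=6), rng.normal(size=6) + 1
            cells = [CELL_A] * 6 + [CELL_B] * 6
            fit = fit_cell_means(np.concatenate([a, b]), cells)
            t, _ = stats.ttest_ind(a, b)
            assert f_statistic(fit, AB) == pytest.approx(t**2)

    def test_scale_invariance(self):
        y = np.array([1.0, 4.0, 2.0, 9.0])
        f1 = f_statistic(fit_cell_means(y, TWO_CELLS), AB)
        f2 = f_statistic(fit_cell_means(7.0 * y, TWO_CELLS), AB)
        assert f1 == pytest.approx(f2)

    def test_zero_residual_zero_estimate(self):
        fit = fit_cell_means(np.full(4, 2.0), TWO_CELLS)
        assert f_statistic(fit, AB) == 0.0

    def test_estimate_and_se_match_pooled_t(self):
        y = np.array([1.0, 3.0, 5.0, 7.0])
        est, se = contrast_estimate(fit_cell_means(y, TWO_CELLS), AB)
        assert est == pytest.approx(-4.0)
        assert se == pytest.approx(np.sqrt(2.0 * (0.5 + 0.5)))


class TestStandardContrasts:
    def test_farm_weights(self, full_design):
        farm = next(c for c in standard_contrasts(full_design)
                    if c.name == "farm")
        pos = [w for w in farm.weights.values() if w > 0]
        neg = [w for w in farm.weights.values() if w < 0]
        assert pos == [pytest.approx(1 / 8)] * 8
        assert neg == [pytest.approx(-1 / 4)] * 4

    def test_weights_sum_to_zero(self, full_design):
        for c in standard_contrasts(full_design):
            assert sum(c.weights.values()) == pytest.approx(0.0, abs=1e-12)

    def test_antibiotic_contrast_excludes_farm_a(self, full_design):
        anti = next(c for c in standard_contrasts(full_design)
                    if c.name == "antibiotic_within_B")
        assert all(cell[0] == "B" for cell in anti.weights)

    def test_unbalanced_parts_rejected(self):
        with pytest.raises(ContrastError):
            Contrast("bad", {CELL_A: 0.5, CELL_B: -1.0})

    def test_unobserved_cell_rejected(self):
        with pytest.raises(ContrastError):
            AB.vector([CELL_A])


class TestPermutationPvalue:
    def test_constant_response_p_one(self):
        assert permutation_pvalue(np.full(4, 1.0), TWO_CELLS, AB,
                                  n_perm=50, seed=0) == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=12)
        cells = [CELL_A] * 6 + [CELL_B] * 6
        p1 = permutation_pvalue(y, cells, AB, n_perm=200, seed=5)
        p2 = permutation_pvalue(3.0 * y - 11.0, cells, AB, n_perm=200, seed=5)
        assert p1 == p2

    def test_uniform_under_exchangeable_null(self):
        """Permutation p-values on iid Gaussian data are uniform on their
        achievable grid (KS test over replicates)."""
        rng = np.random.default_rng(3)
        cells = [CELL_A] * 10 + [CELL_B] * 10
        pvals = [permutation_pvalue(rng.normal(size=20), cells, AB,
                                    n_perm=99, seed=int(rng.integers(2**31)),
                                    add_one=True)
                 for _ in range(500)]
        # smoothed p is uniform on {1/100, ..., 1}; compare to that grid
        grid = (np.floor(np.array(pvals) * 100) / 100)
        assert stats.kstest(grid, "uniform").pvalue > 0.01

    def test_agrees_with_classical_f_on_gaussian_data(self):
        """On balanced Gaussian data the permutation null reproduces the
        theoretical F-test p within Monte-Carlo error."""
        rng = np.random.default_rng(4)
        y = np.concatenate([rng.normal(size=15), rng.normal(size=15) + 0.9])
        cells = [CELL_A] * 15 + [CELL_B] * 15
        fit = fit_cell_means(y, cells)
        p_classical = stats.f.sf(f_statistic(fit, AB), 1, fit.resid_df)
        p_perm = permutation_pvalue(y, cells, AB, n_perm=4000, seed=6)
        assert p_perm == pytest.approx(p_classical, abs=0.02)

    def test_add_one_variant_never_zero(self):
        y = np.concatenate([np.zeros(5), np.ones(5) * 100])
        cells = [CELL_A] * 5 + [CELL_B] * 5
        p = permutation_pvalue(y, cells, AB, n_perm=100, seed=0, add_one=True)
        assert p >= 1 / 101


class TestInteractionTest:
    def _meta(self, n_per_cell):
        rows = []
        for farm, batch in (("A", 1), ("B", 5)):
            for feeding in ("AL", "R"):
                for i in range(n_per_cell):
                    rows.append((f"{farm}{feeding}{i}", farm, batch, "with",
                                 feeding))
        return pd.DataFrame(rows, columns=["sample_id", "farm", "batch",
                                           "antibiotic", "feeding"])

    def test_constant_response_p_one(self):
        meta = self._meta(3)
        res = interaction_test(np.full(12, 5.0), meta, n_perm=50, seed=0)
        assert res["p_emp"] == 1.0

    def test_null_rejection_rate_near_nominal(self):
        """Identical feeding effect in both farms: the interaction test
        rejects at ~ the nominal rate."""
        meta = self._meta(6)
        feeding_eff = (meta.feeding == "R").to_numpy() * 2.0
        rng = np.random.default_rng(8)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            y = feeding_eff + rng.normal(size=len(meta))
            res = interaction_test(y, meta, n_perm=99,
                                   seed=int(rng.integers(2**31)), add_one=True)
            rej += res["p_emp"] <= 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.03)

    def test_detects_farm_specific_feeding_effect(self):
        meta = self._meta(10)
        eff = ((meta.feeding == "R") & (meta.farm == "A")).to_numpy() * 4.0
        rng = np.random.default_rng(9)
        y = eff + rng.normal(scale=0.5, size=len(meta))
        res = interaction_test(y, meta, n_perm=500, seed=1)
        assert res["p_emp"] <= 0.01

    def test_confounded_factors_rejected(self, full_design):
        y = np.zeros(len(full_design))
        with pytest.raises(ContrastError):
            # antibiotic does not vary within farm A -> empty (A, without)
            interaction_test(y, full_design, ("farm", "antibiotic"))


def bh_oracle(p):
    """Literal step-up: largest k with p_(k) <= k/m * alpha defines the
    rejection set; adjusted p by reverse cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_worked_example(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.5])

    def test_single_and_tied_inputs_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_exhaustive_against_step_up_oracle(self):
        """Matches a literal step-up implementation on every p-vector of
        length <= 8 over a 3-point grid."""
        grid = [0.01, 0.25, 0.9]
        for m in range(1, 9):
            for combo in itertools.product(grid, repeat=m):
                assert np.allclose(bh_fdr(combo), bh_oracle(combo))

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.5, 1.2])


class TestRunDifferentialAbundance:
    def _small_dataset(self, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = [(f"S{i}", "A", 1, "with", "AL") for i in range(10)]
        rows += [(f"S{i + 10}", "B", 5, "with", "AL") for i in range(10)]
        meta = pd.DataFrame(rows, columns=["sample_id", "farm", "batch",
                                           "antibiotic", "feeding"])
        X = rng.normal(size=(12, 20))
        X[:3, :10] += effect  # first 3 taxa shifted in farm A
        frame = pd.DataFrame(X, index=[f"T{i}" for i in range(12)],
                             columns=meta.sample_id)
        return frame, meta

    def test_estimates_recover_planted_shift(self):
        frame, meta = self._small_dataset(seed=1, effect=3.0)
        res = run_differential_abundance(frame, meta, n_perm=200, seed=2)
        farm = res[res.contrast == "farm"].set_index("taxon")
        assert farm.loc[["T0", "T1", "T2"], "estimate"].mean() == pytest.approx(
            3.0, abs=0.8)
        assert farm.loc[["T0", "T1", "T2"], "significant"].all()

    def test_present_only_in_one_farm(self):
        """A taxon absent from farm B gets a positive farm estimate with a
        zero farm-B group mean."""
        frame, meta = self._small_dataset(seed=3)
        y = np.zeros(20)
        y[:10] = np.abs(np.random.default_rng(4).normal(2.0, 0.2, 10))
        frame.loc["T5"] = y
        res = run_differential_abundance(frame, meta, n_perm=200, seed=5)
        row = res[(res.taxon == "T5") & (res.contrast == "farm")].iloc[0]
        assert row.estimate > 0
        assert row.mean_neg == pytest.approx(0.0)

    def test_results_independent_of_taxon_order(self):
        frame, meta = self._small_dataset(seed=6, effect=1.0)
        res1 = run_differential_abundance(frame, meta, n_perm=100, seed=7)
        res2 = run_differential_abundance(frame.iloc[::-1], meta, n_perm=100,
                                          seed=7)
        merged = res1.merge(res2, on=["taxon", "contrast"], suffixes=("", "_r"))
        assert np.allclose(merged.p_emp, merged.p_emp_r)
        assert np.allclose(merged.estimate, merged.estimate_r)

    def test_p_fdr_not_below_p_emp(self):
        frame, meta = self._small_dataset(seed=8, effect=0.5)
        res = run_differential_abundance(frame, meta, n_perm=100, seed=9)
        assert (res.p_fdr >= res.p_emp - 1e-12).all()

    def test_sample_mismatch_rejected(self):
        frame, meta = self._small_dataset()
        with pytest.raises(AlignmentError):
            run_differential_abundance(frame.iloc[:, :-1], meta, n_perm=10)

    def test_auto_feeding_mode_runs(self):
        rng = np.random.default_rng(10)
        rows = []
        i = 0
        for farm, batch in (("A", 1), ("B", 5)):
            for feeding in ("AL", "R"):
                for _ in range(5):
                    rows.append((f"S{i}", farm, batch, "with", feeding))
                    i += 1
        meta = pd.DataFrame(rows, columns=["sample_id", "farm", "batch",
                                           "antibiotic", "feeding"])
        frame = pd.DataFrame(rng.normal(size=(3, 20)),
                             index=["T0", "T1", "T2"], columns=meta.sample_id)
        res = run_differential_abundance(frame, meta, n_perm=100, seed=11,
                                         feeding="auto")
        assert set(res.taxon) == {"T0", "T1", "T2"}
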