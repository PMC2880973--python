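"""Error-model fitting, the lambda statistic and the persistence filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasewave import significance as sg
from phasewave.datatypes import ExpressionMatrix, SampleMeta


def brute_force_persistent(lam, lambda0, k):
    """Independent oracle: exhaustive scan for a run of k conditions > lambda0."""
    hits = set()
    for i, row in enumerate(lam):
        run = 0
        for v in row:
            run = run + 1 if (np.isfinite(v) and v > lambda0) else 0
            if run >= k:
                hits.add(i)
                break
    return hits


class TestEstimateErrorParams:
    def test_recovers_planted_scales_within_20pct(self, rng):
        sa, sm = 0.05, 0.10
        mus = rng.uniform(0.5, 4.0, 5000)
        obs = mus[:, None] * (1 + rng.normal(0, sm, (5000, 4))) + rng.normal(0, sa, (5000, 4))
        p = sg.estimate_error_params(obs)
        assert p.sigma_add == pytest.approx(sa, rel=0.20)
        assert p.sigma_mult == pytest.approx(sm, rel=0.20)
        assert p.converged and not p.degenerate

    def test_purely_additive_noise_gives_tiny_sigma_mult(self, rng):
        mus = rng.uniform(0.5, 4.0, 5000)
        obs = mus[:, None] + rng.normal(0, 0.05, (5000, 4))
        p = sg.estimate_error_params(obs)
        assert p.sigma_mult <= 0.01

    def test_zero_noise_flagged_degenerate(self, rng):
        obs = np.repeat(rng.uniform(0.5, 2.0, 500)[:, None], 3, axis=1)
        p = sg.estimate_error_params(obs)
        assert p.degenerate

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError, match="100 genes"):
            sg.estimate_error_params(rng.normal(1, 0.1, (50, 3)))


class TestLambdaStatistic:
    params = sg.ErrorParams(0.05, 0.10)

    def test_ratio_one_everywhere_gives_zero(self):
        assert sg.lambda_statistic(np.ones(4), self.params) == 0.0

    def test_monotone_in_mean_departure(self):
        lam1 = sg.lambda_statistic(np.array([1.2, 1.2]), self.params)
        lam2 = sg.lambda_statistic(np.array([1.4, 1.4]), self.params)
        assert lam2 >= lam1 > 0

    def test_symmetric_departures_both_positive(self):
        up = sg.lambda_statistic(np.array([2.0, 2.0]), self.params)
        down = sg.lambda_statistic(np.array([0.5, 0.5]), self.params)
        assert up > 0 and down > 0

    def test_requires_params_and_replicates(self):
        with pytest.raises(ValueError):
            sg.lambda_statistic(np.ones(3), None)
        with pytest.raises(ValueError, match="2 replicate"):
            sg.lambda_statistic(np.array([1.0]), self.params)

    def test_null_calibration_against_chi2(self, rng):
        """Under the fitted error model, lambda is ~chi2(1): the rejection
        rate at the 95th percentile is 0.05 within Monte-Carlo error."""
        from scipy import stats

        sa, sm = 0.05, 0.10
        x = 1.0 * (1 + rng.normal(0, sm, (10000, 2))) + rng.normal(0, sa, (10000, 2))
        params = sg.ErrorParams(sa, sm)
        m = x.shape[1]
        xbar = x.mean(axis=1)
        lam = m * (xbar - 1.0) ** 2 / params.variance(xbar)
        rate = float(np.mean(lam > stats.chi2(1).ppf(0.95)))
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_dye_swap_invariance_with_orientation_encoded(self, phases7):
        """Globally swapping the two channels toggles the flip flags and
        negates raw ratios; the orientation-corrected matrix and hence the
        lambda values are unchanged."""
        from phasewave import simulate as sim

        m, _ = sim.simulate_expression({"EXP_HIGH": 30, "NULL": 120}, phases7, seed=3)
        corrected = m.log10_ratio.copy()
        flips = np.array([s.dye_flip for s in m.samples])
        raw = np.where(flips[None, :], -corrected, corrected)
        # swap channels: raw ratios invert, orientation flags toggle
        raw_swapped = -raw
        flips_swapped = ~flips
        corrected_again = np.where(flips_swapped[None, :], -raw_swapped, raw_swapped)
        assert np.array_equal(corrected_again, corrected)


class TestLambdaMatrix:
    def test_broadcasts_condition_lambda_to_replicate_columns(self, phases7):
        from phasewave import simulate as sim

        m, _ = sim.simulate_expression({"NULL": 150}, phases7, seed=0)
        by_cond = {}
        for j, s in enumerate(m.samples):
            by_cond.setdefault(s.sample_index, []).append(j)
        for cols in by_cond.values():
            assert np.allclose(m.lam[:, cols[0]], m.lam[:, cols[1]], equal_nan=True)

    def test_single_replicate_gives_missing(self):
        samples = [SampleMeta("S", "A", i, False, 0.1 * (i + 1)) for i in range(3)]
        m = ExpressionMatrix([f"g{i}" for i in range(120)], samples,
                             np.random.default_rng(0).normal(0, 0.1, (120, 3)))
        lam = sg.lambda_matrix(m, sg.ErrorParams(0.05, 0.1))
        assert np.all(np.isnan(lam))


class TestPersistentSet:
    def test_boundary_run_of_exactly_k(self):
        lam = np.array([[16, 16, 16, 16, 0, 0, 0]], float)
        assert sg.persistent_significant_set(lam, ["g"], 15, 4) == {"g"}

    def test_interrupted_run_excluded(self):
        lam = np.array([[20, 20, 20, 14, 20, 20, 20]], float)
        assert sg.persistent_significant_set(lam, ["g"], 15, 4) == set()

    def test_threshold_is_strict(self):
        lam = np.full((1, 7), 15.0)
        assert sg.persistent_significant_set(lam, ["g"], 15, 4) == set()

    def test_missing_lambda_breaks_runs(self):
        lam = np.array([[20, 20, np.nan, 20, 20, 20, 0]], float)
        assert sg.persistent_significant_set(lam, ["g"], 15, 4) == set()
        lam2 = np.array([[20, 20, np.nan, 20, 20, 20, 20]], float)
        assert sg.persistent_significant_set(lam2, ["g"], 15, 4) == {"g"}

    def test_runs_do_not_cross_strain_boundaries(self):
        lam = np.array([[20, 20, 20, 20]], float)
        strains = ["a", "a", "b", "b"]
        assert sg.persistent_significant_set(lam, ["g"], 15, 2, strains) == {"g"}
        lam2 = np.array([[0, 20, 20, 0]], float)
        assert sg.persistent_significant_set(lam2, ["g"], 15, 2, strains) == set()

    def test_k_larger_than_conditions_rejected(self):
        with pytest.raises(ValueError, match="k=9"):
            sg.persistent_significant_set(np.zeros((2, 5)), None, 15, 9)

    def test_matches_exhaustive_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            lam = rng.exponential(10, (50, 10))
            lam[rng.random((50, 10)) < 0.05] = np.nan
            k = int(rng.integers(1, 6))
            lambda0 = float(rng.uniform(5, 25))
            got = sg.persistent_significant_set(lam, None, lambda0, k)
            assert got == brute_force_persistent(lam, lambda0, k)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed):
        r = np.random.default_rng(seed)
        lam = r.exponential(12, (20, 8))
        got = sg.persistent_significant_set(lam, None, 15, 3)
        assert got == brute_force_persistent(lam, 15, 3)


class TestThresholdSweep:
    def test_counts_monotone_in_both_arguments(self, rng):
        lam = rng.exponential(10, (200, 10))
        table = sg.threshold_sweep(lam, [15, 12, 10, 7], [4, 3, 2, 1], 400)
        for k in (4, 3, 2, 1):
            counts = table[table["k"] == k].sort_values("lambda0")["gene_count"].to_numpy()
            assert np.all(np.diff(counts) <= 0)
        for l0 in (15.0, 12.0, 10.0, 7.0):
            counts = table[table["lambda0"] == l0].sort_values("k")["gene_count"].to_numpy()
            assert np.all(np.diff(counts) <= 0)

    def test_all_zero_matrix_gives_empty_counts(self):
        table = sg.threshold_sweep(np.zeros((30, 8)), [15.0], [4, 3, 2, 1], 30)
        assert (table["gene_count"] == 0).all()
        assert (table["fraction"] == 0).all()

    def test_fraction_uses_total_gene_count(self, rng):
        lam = np.full((10, 8), 30.0)
        table = sg.threshold_sweep(lam, [15.0], [4], 40)
        assert table["gene_count"].iloc[0] == 10
        assert table["fraction"].iloc[0] == pytest.approx(0.25)

    def test_universe_smaller_than_matrix_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            sg.threshold_sweep(np.zeros((30, 8)), [15.0], [4], 10)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sg.threshold_sweep(np.zeros((3, 8)), [], [4], 3)
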