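"""Determinism, construction guarantees and truth recovery of the simulators."""

import numpy as np
import pytest
from scipy import stats

from phasewave import patterns, significance
from phasewave import simulate as sim


class TestGrowthSimulator:
    def test_first_od_equals_inoculation_density(self):
        c = sim.simulate_growth_curve(od0=0.02, n_points=10, t_span=50)
        assert c.od600[0] == pytest.approx(0.02, rel=1e-6)

    def test_noiseless_curve_monotone_and_bounded(self):
        c = sim.simulate_growth_curve(
            mu_max=0.3, od0=0.02, od_max=1.0, secondary_rise=0.0, n_points=50, t_span=60
        )
        assert np.all(np.diff(c.od600) >= 0)
        assert np.all(c.od600 <= 1.0 + 1e-9)

    def test_secondary_rise_adds_late_od(self):
        base = sim.simulate_growth_curve(n_points=30, t_span=80, secondary_rise=0.0)
        risen = sim.simulate_growth_curve(n_points=30, t_span=80, secondary_rise=0.2)
        assert risen.od600[-1] > base.od600[-1] + 0.1
        assert risen.od600[0] == pytest.approx(base.od600[0], rel=1e-6)

    def test_same_seed_identical(self):
        a = sim.simulate_growth_curve(noise_cv=0.05, seed=9, n_points=12, t_span=50)
        b = sim.simulate_growth_curve(noise_cv=0.05, seed=9, n_points=12, t_span=50)
        assert np.array_equal(a.od600, b.od600)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            sim.simulate_growth_curve(n_points=3)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sim.simulate_growth_curve(mu_max=-0.1)
        with pytest.raises(ValueError):
            sim.simulate_growth_curve(od0=2.0, od_max=1.0)


class TestExpressionSimulator:
    def test_same_seed_identical(self, phases7):
        a, _ = sim.simulate_expression({"EXP_HIGH": 20, "NULL": 100}, phases7, seed=5)
        b, _ = sim.simulate_expression({"EXP_HIGH": 20, "NULL": 100}, phases7, seed=5)
        assert a == b

    def test_noiseless_template_ordering(self, phases7):
        m, truth = sim.simulate_expression(
            {"EXP_HIGH": 10, "NULL": 110}, phases7, effect=1.0, sigma_add=0.0, sigma_mult=0.0, seed=0
        )
        exp_cols = [j for j, s in enumerate(m.samples)
                    if phases7.label_for_index(s.sample_index) == "EXPONENTIAL"]
        stat_cols = [j for j, s in enumerate(m.samples)
                     if phases7.label_for_index(s.sample_index) == "STATIONARY"]
        for g in truth.non_null_genes():
            row = m.gene_row(g)
            assert row[exp_cols].mean() > row[stat_cols].mean()

    def test_null_only_matrix_yields_no_persistent_calls(self, phases7):
        m, _ = sim.simulate_expression(
            {"NULL": 100}, phases7, sigma_add=0.05, sigma_mult=0.05, seed=1
        )
        called = significance.persistent_significant_genes(m, lambda0=15, k=4)
        # chi2(1) tail beyond 15 is ~1e-4 per condition; a run of 4 is
        # essentially impossible among 100 null genes
        assert len(called) <= 1

    def test_lambda_computed_from_replicate_structure(self, phases7):
        m, _ = sim.simulate_expression({"EXP_HIGH": 30, "NULL": 90}, phases7, seed=2)
        assert m.lam is not None
        assert m.lam.shape == m.shape
        assert np.nanmin(m.lam) >= 0

    def test_empty_request_rejected(self, phases7):
        with pytest.raises(ValueError, match="zero genes"):
            sim.simulate_expression({}, phases7)

    def test_unknown_class_rejected(self, phases7):
        with pytest.raises(ValueError, match="unknown archetype"):
            sim.simulate_expression({"WIGGLY": 5}, phases7)


class TestMorphologySimulator:
    def test_degenerate_weight_single_component(self):
        table, _ = sim.simulate_morphology([(0.0, 0.4, 0.9, 0.05, 0.05)], n_cells=300, seed=0)
        assert (table["component"] == 1).all()
        assert abs(table["circularity"].mean() - 0.4) < 0.02

    def test_component_fraction_within_binomial_interval(self):
        n, w2 = 500, 0.4
        table, _ = sim.simulate_morphology([(w2, 0.35, 0.85, 0.08, 0.05)], n_cells=n, seed=7)
        frac = (table["component"] == 2).mean()
        lo, hi = stats.binom(n, w2).ppf([0.005, 0.995]) / n
        assert lo <= frac <= hi

    def test_same_seed_identical(self):
        a, _ = sim.simulate_morphology([(0.3, 0.4, 0.8, 0.06, 0.05)], n_cells=100, seed=3)
        b, _ = sim.simulate_morphology([(0.3, 0.4, 0.8, 0.06, 0.05)], n_cells=100, seed=3)
        assert a.equals(b)

    def test_circularity_truncated_to_unit_interval(self):
        table, _ = sim.simulate_morphology([(0.5, 0.1, 0.95, 0.3, 0.2)], n_cells=2000, seed=1)
        assert table["circularity"].between(0, 1, inclusive="right").all()

    def test_low_circularity_means_high_aspect(self):
        table, _ = sim.simulate_morphology([(0.5, 0.3, 0.9, 0.05, 0.04)], n_cells=500, seed=2)
        aspect = table["major_axis"] / table["minor_axis"]
        r = np.corrcoef(table["circularity"], aspect)[0, 1]
        assert r < -0.8

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError, match="w2"):
            sim.simulate_morphology([(1.2, 0.4, 0.8, 0.05, 0.05)], n_cells=10)


class TestMetaboliteSimulator:
    def test_noiseless_concordant_features_pass_fold_filter(self):
        from phasewave import metabolites as mb

        tbl, truth = sim.simulate_metabolites(n_features=20, n_concordant=5, fold=4, noise_cv=0.0, seed=0)
        res = mb.filter_significant_features(tbl)
        for fid in truth.concordant_features:
            assert res.loc[fid, "fold"] >= 3.0

    def test_noiseless_profile_matches_planted_exactly(self):
        from phasewave import metabolites as mb

        tbl, truth = sim.simulate_metabolites(n_features=5, n_concordant=2, noise_cv=0.0, seed=0)
        profile = mb.feature_phase_profile(tbl, truth.concordant_features[0])
        assert mb.concordance_score(profile, truth.metabolite_profile) == pytest.approx(1.0)

    def test_same_seed_identical(self):
        a, _ = sim.simulate_metabolites(n_features=10, n_concordant=2, seed=4)
        b, _ = sim.simulate_metabolites(n_features=10, n_concordant=2, seed=4)
        assert a.equals(b)

    def test_too_many_concordant_rejected(self):
        with pytest.raises(ValueError, match="n_concordant"):
            sim.simulate_metabolites(n_features=5, n_concordant=6)


class TestStudyBundle:
    def test_default_design_shape(self, study):
        assert study.expression.shape == (2400, 26)
        assert study.expression.strains() == ["MPK407", "NRC-1"]
        assert len(study.growth_curves) == 4

    def test_class_sizes_sum_to_genome(self, study):
        from collections import Counter

        counts = Counter(study.truth.archetype_of.values())
        assert sum(counts.values()) == 2400
        assert counts["EXP_HIGH"] == 451
        assert counts["STAT_HIGH"] == 772

    def test_archetype_recovery_meets_planted_target(self, study):
        """At effect 1.0 and sigma 0.1 the full chain (filter, normalize,
        cluster, classify) recovers >= 90% of planted non-null labels."""
        sig = significance.persistent_significant_genes(study.expression)
        wt = study.expression.subset_strain("NRC-1").subset_genes(sorted(sig))
        norm = patterns.row_normalize(wt)
        res = patterns.cluster_profiles(norm, k=10, seed=1)
        res = patterns.classify_clusters(
            res, study.phases["NRC-1"], [s.sample_index for s in wt.samples]
        )
        non_null = study.truth.non_null_genes()
        correct = sum(
            1 for g in non_null
            if g in res.gene_cluster
            and res.cluster_labels[res.gene_cluster[g]] == study.truth.archetype_of[g]
        )
        assert correct / len(non_null) >= 0.90

    def test_annotation_covers_genome_with_plasmid_share(self, study):
        plasmid = study.annotation.plasmid_genes()
        assert set(study.annotation.replicon_of) == set(study.expression.gene_ids)
        assert 0.15 <= len(plasmid) / 2400 <= 0.25

    def test_study_deterministic(self):
        a = sim.simulate_study(seed=42, class_sizes={"EXP_HIGH": 30, "STAT_HIGH": 40, "NULL": 130},
                               n_strain_diff=5, n_cells=60, n_metab_features=20, n_metab_concordant=3)
        b = sim.simulate_study(seed=42, class_sizes={"EXP_HIGH": 30, "STAT_HIGH": 40, "NULL": 130},
                               n_strain_diff=5, n_cells=60, n_metab_features=20, n_metab_concordant=3)
        assert a.expression == b.expression
        assert a.morphology.equals(b.morphology)
        assert a.metabolites.equals(b.metabolites)
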