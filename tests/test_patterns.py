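"""Row normalization, archetype classification, clustering, enrichment."""

from math import comb

import numpy as np
import pytest

from phasewave import patterns
from phasewave.datatypes import ExpressionMatrix, GenomeAnnotation, SampleMeta
from phasewave import simulate as sim


def matrix_from(data, gene_ids=None):
    data = np.asarray(data, float)
    n, m = data.shape
    samples = [SampleMeta("S", "A", j, False, 0.1 * (j + 1)) for j in range(m)]
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    return ExpressionMatrix(gene_ids, samples, data)


class TestRowNormalize:
    def test_hand_computed_row(self):
        norm = patterns.row_normalize(matrix_from([[1.0, 2.0, 3.0]]))
        assert np.allclose(norm.log10_ratio[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent(self, rng):
        m = matrix_from(rng.normal(0, 1, (20, 8)))
        once = patterns.row_normalize(m)
        twice = patterns.row_normalize(once)
        assert np.allclose(once.log10_ratio, twice.log10_ratio, atol=1e-12)

    def test_constant_row_names_gene(self):
        with pytest.raises(ValueError, match="gBAD"):
            patterns.row_normalize(matrix_from([[5.0, 5.0, 5.0]], gene_ids=["gBAD"]))

    def test_missing_values_preserved(self):
        m = matrix_from([[1.0, np.nan, 2.0, 3.0]])
        norm = patterns.row_normalize(m)
        assert np.isnan(norm.log10_ratio[0, 1])
        observed = norm.log10_ratio[0, [0, 2, 3]]
        assert observed.mean() == pytest.approx(0.0, abs=1e-12)
        assert observed.std() == pytest.approx(1.0, abs=1e-12)


class TestClusterProfiles:
    def test_k1_centroid_is_column_means(self, rng):
        m = matrix_from(rng.normal(0, 1, (30, 5)))
        res = patterns.cluster_profiles(m, k=1, seed=0)
        assert set(res.gene_cluster.values()) == {0}
        assert np.allclose(res.centroids[0], m.log10_ratio.mean(axis=0))

    def test_duplicated_rows_share_cluster(self, rng):
        base = rng.normal(0, 1, (10, 6))
        data = np.vstack([base, base[0]])
        res = patterns.cluster_profiles(matrix_from(data), k=3, seed=0)
        assert res.gene_cluster["g0"] == res.gene_cluster["g10"]

    def test_deterministic_given_seed(self, rng):
        m = matrix_from(rng.normal(0, 1, (60, 6)))
        a = patterns.cluster_profiles(m, k=4, seed=9)
        b = patterns.cluster_profiles(m, k=4, seed=9)
        assert a.gene_cluster == b.gene_cluster
        assert a.inertia == b.inertia

    def test_k_exceeding_genes_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            patterns.cluster_profiles(matrix_from(rng.normal(0, 1, (4, 3))), k=5, seed=0)

    def test_recovers_planted_partition(self, phases7):
        """Five well-separated planted archetypes, K=5: >= 90% agreement with
        the planted partition after optimal label matching."""
        from scipy.optimize import linear_sum_assignment

        sizes = {c: 60 for c in sim.ARCHETYPE_TEMPLATES if c != "NULL"}
        m, truth = sim.simulate_expression(sizes, phases7, effect=1.0,
                                           sigma_add=0.05, sigma_mult=0.05, seed=2)
        norm = patterns.row_normalize(m)
        res = patterns.cluster_profiles(norm, k=5, seed=2)
        classes = sorted(set(truth.archetype_of.values()))
        conf = np.zeros((5, 5), int)
        for g, c in res.gene_cluster.items():
            conf[c, classes.index(truth.archetype_of[g])] += 1
        rows, cols = linear_sum_assignment(-conf)
        agreement = conf[rows, cols].sum() / len(res.gene_cluster)
        assert agreement >= 0.90


class TestClassifyArchetype:
    PH = ["EARLY", "EXPONENTIAL", "TRANSITION", "STATIONARY"]

    @pytest.mark.parametrize(
        "segments,expected",
        [
            ((0, 1, 0, -1), "TRANSIENT_UP_EXP"),  # pulse precedence over EXP_HIGH
            ((0, -1, 0, 1), "TRANSIENT_DOWN_EXP"),
            ((0, 0, 0, 0), "OTHER"),
            ((1, 1, 0, -1), "EXP_HIGH"),
            ((-1, -1, 0, 1), "STAT_HIGH"),
            ((0, 0, 1, 0), "TRANSIENT_UP_TRANSITION"),
            ((0, 0.2, 0, -0.2), "OTHER"),  # all differences below the margin
        ],
    )
    def test_rule_table(self, segments, expected):
        assert patterns.classify_archetype(np.array(segments, float), self.PH) == expected

    def test_shift_invariant(self, rng):
        centroid = rng.normal(0, 1, 4)
        a = patterns.classify_archetype(centroid, self.PH)
        b = patterns.classify_archetype(centroid + 7.3, self.PH)
        assert a == b

    def test_missing_segment_skips_rule(self):
        # no TRANSITION column: the transition-pulse rule is skipped, the
        # remaining rules still apply
        label = patterns.classify_archetype(
            np.array([1.0, 1.0, -1.0]), ["EARLY", "EXPONENTIAL", "STATIONARY"]
        )
        assert label == "EXP_HIGH"

    def test_margin_configurable(self):
        # X - E = X - S = 0.4: below the default margin, above a loose one
        centroid = np.array([0.0, 0.4, 0.0, 0.0])
        assert patterns.classify_archetype(centroid, self.PH, delta=0.5) == "OTHER"
        assert patterns.classify_archetype(centroid, self.PH, delta=0.3) == "TRANSIENT_UP_EXP"


def brute_force_hypergeom_tail(N, K, n, k, upper):
    """Oracle: exact tail from binomial coefficients."""
    total = comb(N, n)
    ks = range(k, min(n, K) + 1) if upper else range(max(0, n - (N - K)), k + 1)
    return sum(comb(K, j) * comb(N - K, n - j) for j in ks) / total


class TestRepliconEnrichment:
    def test_extreme_overlap_exact_value(self):
        universe = GenomeAnnotation(
            {f"g{i}": ("pNRC200" if i < 10 else "Chromosome") for i in range(20)}
        )
        gene_set = {f"g{i}" for i in range(10)}
        res = patterns.replicon_enrichment(gene_set, universe.plasmid_genes(), universe)
        assert res.direction == "over"
        assert res.p_value == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_expected_overlap_gives_large_p(self):
        universe = GenomeAnnotation(
            {f"g{i}": ("pNRC100" if i < 10 else "Chromosome") for i in range(20)}
        )
        gene_set = {f"g{i}" for i in list(range(5)) + list(range(10, 15))}  # k/n = K/N
        res = patterns.replicon_enrichment(gene_set, universe.plasmid_genes(), universe)
        assert res.p_value > 0.5

    def test_matches_brute_force_for_all_small_universes(self):
        for N in range(2, 16):
            for K in range(1, N):
                for n in range(1, N + 1):
                    for k in range(max(0, n - (N - K)), min(n, K) + 1):
                        res = patterns.replicon_enrichment(
                            set(range(k)) | set(range(K, K + n - k)),
                            set(range(K)),
                            N,
                        )
                        upper = res.direction == "over"
                        oracle = brute_force_hypergeom_tail(N, K, n, k, upper)
                        assert res.p_value == pytest.approx(oracle, rel=1e-9), (N, K, n, k)

    def test_over_tail_monotone_in_overlap(self):
        universe = 100
        category = set(range(30))
        pvals = []
        for k in (15, 20, 25):
            gene_set = set(range(k)) | set(range(30, 30 + 30 - k))
            res = patterns.replicon_enrichment(gene_set, category, universe)
            assert res.direction == "over"
            pvals.append(res.p_value)
        assert pvals == sorted(pvals, reverse=True)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            patterns.replicon_enrichment(set(), {"g1"}, 10)
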