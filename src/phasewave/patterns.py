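"""Temporal expression archetypes and replicon enrichment.

Filtered genes are row-normalized (mean 0, sd 1 per gene), clustered with
K-means, and each cluster centroid is classified into one of five temporal
archetypes defined by its phase-segment means E (EARLY), X (EXPONENTIAL),
T (TRANSITION) and S (STATIONARY):

* ``EXP_HIGH``                — high in exponential growth, strongly reduced
  in stationary phase (X - S >= delta, not a pulse);
* ``STAT_HIGH``               — induced upon entry into stationary phase;
* ``TRANSIENT_UP_EXP``        — pulse up during exponential growth;
* ``TRANSIENT_DOWN_EXP``      — pulse down during exponential growth;
* ``TRANSIENT_UP_TRANSITION`` — pulse up at the exponential/stationary
  transition;
* ``OTHER``                   — none of the above at margin delta.

Transient (pulse) rules are checked before the monotone rules so a pulse is
never mislabelled as a step.  All rules compare segment differences only,
so the labels are invariant to adding a constant to a centroid.

Enrichment of a gene set in a replicon (or any gene category) is tested
with the exact hypergeometric tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .datatypes import ExpressionMatrix, GenomeAnnotation
from .growth import PhaseAnnotation, PHASES

__all__ = [
    "ARCHETYPES",
    "ArchetypeResult",
    "EnrichmentResult",
    "row_normalize",
    "cluster_profiles",
    "classify_archetype",
    "classify_clusters",
    "replicon_enrichment",
]

log = logging.getLogger(__name__)

ARCHETYPES = (
    "EXP_HIGH",
    "STAT_HIGH",
    "TRANSIENT_UP_EXP",
    "TRANSIENT_DOWN_EXP",
    "TRANSIENT_UP_TRANSITION",
    "OTHER",
)


@dataclass
class ArchetypeResult:
    """K-means partition of filtered genes plus per-cluster archetype labels."""

    gene_cluster: dict[str, int]
    centroids: np.ndarray  # (K, n_samples) in normalized units
    cluster_labels: dict[int, str] = field(default_factory=dict)
    delta: float = 0.5
    k: int = 0
    seed: int = 0
    n_restarts: int = 0
    inertia: float = float("nan")

    def genes_with_label(self, label: str) -> set[str]:
        clusters = {c for c, l in self.cluster_labels.items() if l == label}
        return {g for g, c in self.gene_cluster.items() if c in clusters}

    def label_counts(self) -> dict[str, int]:
        counts = {a: 0 for a in ARCHETYPES}
        for g, c in self.gene_cluster.items():
            counts[self.cluster_labels.get(c, "OTHER")] += 1
        return counts


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of a gene set in a category.

    N genes in the universe, K in the category, n in the query set, k in
    both.  ``direction`` is "over" when the set is enriched (k/n > K/N) and
    "under" otherwise; ``p_value`` is the corresponding exact tail.
    """

    n_universe: int
    n_category: int
    n_set: int
    n_overlap: int
    p_value: float
    direction: str


def row_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene row to mean 0 and (population) sd 1.

    Missing cells are ignored in the statistics and stay missing.  A row
    with zero variance cannot be normalized; the error names the gene.
    """
    x = matrix.log10_ratio.copy()
    finite = np.isfinite(x)
    n = finite.sum(axis=1)
    if np.any(n < 2):
        g = matrix.gene_ids[int(np.argmax(n < 2))]
        raise ValueError(f"gene {g!r} has fewer than 2 observed values")
    mean = np.nansum(np.where(finite, x, 0.0), axis=1) / n
    centered = x - mean[:, None]
    sd = np.sqrt(np.nansum(np.where(finite, centered * centered, 0.0), axis=1) / n)
    zero = sd <= 0
    if np.any(zero):
        g = matrix.gene_ids[int(np.argmax(zero))]
        raise ValueError(f"gene {g!r} has constant expression (zero variance)")
    return ExpressionMatrix(matrix.gene_ids, matrix.samples, centered / sd[:, None], matrix.lam)


def cluster_profiles(
    normalized: ExpressionMatrix,
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 25,
) -> ArchetypeResult:
    """Best-of-restarts K-means partition of normalized gene profiles.

    Uses k-means++ seeding with ``n_restarts`` independent starts and keeps
    the assignment with the lowest within-cluster sum of squares; the result
    is deterministic given the seed.  Missing cells are imputed as 0 (the
    row mean in normalized units) for the distance computation only.
    """
    if k < 1:
        raise ValueError("cluster count K must be >= 1")
    if k > normalized.n_genes:
        raise ValueError(f"K={k} exceeds the {normalized.n_genes} genes available")
    x = np.nan_to_num(normalized.log10_ratio, nan=0.0)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(x)
    return ArchetypeResult(
        gene_cluster={g: int(c) for g, c in zip(normalized.gene_ids, assign)},
        centroids=km.cluster_centers_,
        delta=float("nan"),
        k=k,
        seed=seed,
        n_restarts=n_restarts,
        inertia=float(km.inertia_),
    )


def _segment_means(
    centroid: np.ndarray, phase_of_column: list[str]
) -> dict[str, float]:
    means: dict[str, float] = {}
    arr = np.asarray(centroid, dtype=float)
    for phase in PHASES:
        idx = [j for j, p in enumerate(phase_of_column) if p == phase]
        vals = arr[idx]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            means[phase] = float(np.mean(vals))
    return means


def classify_archetype(
    centroid: np.ndarray,
    phase_of_column: list[str],
    delta: float = 0.5,
) -> str:
    """Classify one centroid profile into an archetype.

    ``phase_of_column`` gives the growth phase of each column of the
    centroid.  Rules use phase-segment mean differences with margin
    ``delta`` (normalized units); a rule whose required segment is absent
    from the design is skipped (and logged).  Precedence: the three
    transient (pulse) classes, then EXP_HIGH, then STAT_HIGH.
    """
    m = _segment_means(centroid, phase_of_column)
    E, X, T, S = (m.get(p) for p in PHASES)

    def have(*vals) -> bool:
        return all(v is not None for v in vals)

    rules = [
        ("TRANSIENT_UP_EXP", (X, E, S), lambda: X - E >= delta and X - S >= delta),
        ("TRANSIENT_DOWN_EXP", (X, E, S), lambda: E - X >= delta and S - X >= delta),
        ("TRANSIENT_UP_TRANSITION", (T, X, S), lambda: T - X >= delta and T - S >= delta),
        ("EXP_HIGH", (X, E, S), lambda: X - S >= delta and X >= E - delta),
        ("STAT_HIGH", (X, S), lambda: S - X >= delta),
    ]
    for name, needed, rule in rules:
        if not have(*needed):
            log.debug("archetype rule %s skipped: required phase segment absent", name)
            continue
        if rule():
            return name
    return "OTHER"


def classify_clusters(
    result: ArchetypeResult,
    phases: PhaseAnnotation,
    sample_indices: list[int],
    delta: float = 0.5,
) -> ArchetypeResult:
    """Label every cluster of a K-means result with its archetype.

    ``sample_indices`` maps each centroid column to its position along the
    growth curve so phase labels can be looked up in the annotation.
    """
    phase_of_column = [phases.label_for_index(i) for i in sample_indices]
    labels = {
        c: classify_archetype(result.centroids[c], phase_of_column, delta)
        for c in range(result.centroids.shape[0])
    }
    result.cluster_labels = labels
    result.delta = delta
    return result


def replicon_enrichment(
    gene_set: set[str],
    category: set[str],
    universe: GenomeAnnotation | int,
) -> EnrichmentResult:
    """Exact hypergeometric enrichment of ``gene_set`` in ``category``.

    ``universe`` is either a :class:`GenomeAnnotation` (N = its total gene
    count, and membership of set/category in the universe is checked) or a
    plain integer N.  The upper tail P(X >= k) is reported when the set is
    over-represented (k/n > K/N), the lower tail P(X <= k) otherwise.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    if isinstance(universe, GenomeAnnotation):
        universe.require_genes(gene_set)
        universe.require_genes(category)
        n_universe = int(universe.total_genes)
    else:
        n_universe = int(universe)
    n_cat = len(category)
    n_set = len(gene_set)
    if n_set > n_universe or n_cat > n_universe:
        raise ValueError("set or category larger than the universe")
    k = len(gene_set & category)
    hg = stats.hypergeom(n_universe, n_cat, n_set)
    if k * n_universe > n_cat * n_set:
        direction = "over"
        p = float(hg.sf(k - 1))
    else:
        direction = "under"
        p = float(hg.cdf(k))
    p = min(1.0, max(p, 0.0))
    return EnrichmentResult(n_universe, n_cat, n_set, k, p, direction)
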