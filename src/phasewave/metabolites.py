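"""Metabolite phase profiles and transcript-metabolite concordance.

Metabolite features (LC-MS peaks) are measured in replicate at three
harvests — early growth, exponential growth and stationary phase.  Features
are retained when the early-vs-stationary change is both statistically
significant (Student t test on log abundances, p < 0.001 by default) and at
least 3-fold in either direction.  The pooled-variance Student form is used
rather than Welch because replicate counts are tiny (triplicates) and equal
design variance is part of the measurement model; with equal group sizes
the statistic is identical and only the reference degrees of freedom
differ.  A retained feature's standardized
three-phase profile is compared with the phase-averaged expression profile
of a gene group by Pearson correlation (the concordance score), the logic
behind matching, e.g., a high-low-high metabolite to the enzymes that
consume and produce it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix
from .growth import PhaseAnnotation

__all__ = [
    "METABOLITE_PHASES",
    "phase_aggregate",
    "standardize_profile",
    "filter_significant_features",
    "concordance_score",
    "concordance_matrix",
]

log = logging.getLogger(__name__)

#: Phases at which metabolites are harvested.  TRANSITION samples exist in
#: the expression design but not in the three-point metabolite design.
METABOLITE_PHASES = ("EARLY", "EXPONENTIAL", "STATIONARY")


def standardize_profile(values: np.ndarray) -> np.ndarray:
    """Scale a three-phase profile to mean 0, population sd 1."""
    v = np.asarray(values, dtype=float)
    if v.size != 3 or not np.all(np.isfinite(v)):
        raise ValueError("profile must be 3 finite phase values")
    sd = float(np.std(v))
    if sd == 0:
        raise ValueError("profile has zero variance across phases")
    return (v - v.mean()) / sd


def phase_aggregate(
    matrix: ExpressionMatrix,
    phases: PhaseAnnotation,
    genes: set[str] | list[str],
) -> np.ndarray:
    """Standardized three-phase expression profile of a gene group.

    The mean non-logged ratio of the group is computed over the samples in
    each of EARLY, EXPONENTIAL and STATIONARY (sample phase looked up by
    sample_index in the annotation), then standardized to mean 0, sd 1
    across the three phases.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene set is empty")
    sub = matrix.subset_genes(genes)
    ratios = np.power(10.0, sub.log10_ratio)
    means = []
    for phase in METABOLITE_PHASES:
        cols = [
            j for j, s in enumerate(sub.samples)
            if phases.label_for_index(s.sample_index) == phase
        ]
        if not cols:
            raise ValueError(f"no samples fall in phase {phase}")
        means.append(float(np.nanmean(ratios[:, cols])))
    return standardize_profile(np.array(means))


def _phase_stats(feature_rows: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for phase in METABOLITE_PHASES:
        vals = feature_rows.loc[feature_rows["phase"] == phase, "abundance"].to_numpy(float)
        out[phase] = vals[np.isfinite(vals)]
    return out


def filter_significant_features(
    features: pd.DataFrame,
    p_threshold: float = 0.001,
    min_fold: float = 3.0,
) -> pd.DataFrame:
    """Apply the significance and fold filters to a metabolite table.

    ``features`` is tidy with columns ``feature_id``, ``phase``,
    ``replicate``, ``abundance`` (plus optional ``mz``/``rt_min``).  A
    feature is retained iff the Student t test on log10 abundances between
    EARLY and STATIONARY gives p < ``p_threshold`` and the phase-mean fold
    change max(mS/mE, mE/mS) is >= ``min_fold`` (inclusive).  A zero phase
    mean opposite a positive one gives an infinite fold, which passes the
    fold criterion (logged).

    Returns one row per feature with columns ``p``, ``fold``, ``retained``.
    """
    required = {"feature_id", "phase", "abundance"}
    if not required <= set(features.columns):
        raise ValueError(f"features table must have columns {sorted(required)}")
    rows = []
    for fid, grp in features.groupby("feature_id", sort=True):
        ph = _phase_stats(grp)
        early, stat = ph["EARLY"], ph["STATIONARY"]
        if early.size < 2 or stat.size < 2:
            raise ValueError(f"feature {fid!r} needs >= 2 replicates in EARLY and STATIONARY")
        if np.any(early < 0) or np.any(stat < 0):
            raise ValueError(f"feature {fid!r} has negative abundances")
        m_e, m_s = float(np.mean(early)), float(np.mean(stat))
        if m_e == 0 and m_s == 0:
            fold = 1.0
        elif m_e == 0 or m_s == 0:
            fold = float("inf")
            log.info("feature %s: zero phase mean, fold treated as +inf", fid)
        else:
            fold = max(m_s / m_e, m_e / m_s)
        # log transform with half-minimum replacement for exact zeros
        pooled = np.concatenate([early, stat])
        positive = pooled[pooled > 0]
        eps = 0.5 * positive.min() if positive.size else 1.0
        le = np.log10(np.maximum(early, eps))
        ls = np.log10(np.maximum(stat, eps))
        if np.ptp(le) == 0 and np.ptp(ls) == 0:
            p = 1.0 if np.allclose(le.mean(), ls.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(le, ls, equal_var=True).pvalue)
        rows.append(
            {
                "feature_id": fid,
                "p": p,
                "fold": fold,
                "retained": bool(p < p_threshold and fold >= min_fold),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def feature_phase_profile(features: pd.DataFrame, feature_id: str) -> np.ndarray:
    """Standardized three-phase mean-abundance profile of one feature."""
    grp = features[features["feature_id"] == feature_id]
    if grp.empty:
        raise KeyError(f"unknown feature {feature_id!r}")
    means = [float(np.mean(_phase_stats(grp)[p])) for p in METABOLITE_PHASES]
    return standardize_profile(np.array(means))


def concordance_score(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson correlation of two three-phase profiles (in [-1, 1]).

    Symmetric in its arguments and invariant to affine rescaling of either
    profile; raises on zero-variance input.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.size != 3 or b.size != 3:
        raise ValueError("profiles must have length 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("profiles must be finite")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance profile")
    r = float(np.corrcoef(a, b)[0, 1])
    return max(-1.0, min(1.0, r))


def concordance_matrix(
    features: pd.DataFrame,
    feature_ids: list[str],
    gene_profiles: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Concordance scores for every (feature, gene group) pair."""
    out = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"), columns=list(gene_profiles), dtype=float)
    for fid in feature_ids:
        fp = feature_phase_profile(features, fid)
        for gname, gp in gene_profiles.items():
            out.loc[fid, gname] = concordance_score(fp, gp)
    return out
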