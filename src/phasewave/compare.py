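"""Fold changes over growth and differential tests between strains.

``fold_change`` follows the growth-curve convention of comparing the
average non-logged ratio over the last four growth-ordered samples
(replicates included) against the first four.

``permutation_differential`` is a per-gene two-sample t test on logged
values whose p-values come from permuting sample labels, combined with a
permutation-estimated false-significant-proportion step: the significant
set is the largest |t|-threshold set whose estimated proportion of false
significants does not exceed ``max_false_prop``, restricted to genes with
permutation p <= alpha.

``endpoint_change_test`` asks for each gene whether the first-four and
last-four samples differ (t test on logged data) with Benjamini-Hochberg
false-discovery-rate control across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

__all__ = [
    "DifferentialResult",
    "fold_change",
    "fold_changes",
    "permutation_differential",
    "endpoint_change_test",
]

log = logging.getLogger(__name__)


def fold_changes(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene fold change: mean non-logged ratio of the last four samples
    over the mean of the first four, in growth (stored column) order."""
    if matrix.n_samples < 8:
        raise ValueError("fold change needs at least 8 samples (first and last four)")
    ratios = np.power(10.0, matrix.log10_ratio)
    first = np.nanmean(ratios[:, :4], axis=1)
    last = np.nanmean(ratios[:, -4:], axis=1)
    return pd.Series(last / first, index=matrix.gene_ids, name="fold_change")


def fold_change(matrix: ExpressionMatrix, gene_id: str) -> float:
    """Fold change of a single gene (see :func:`fold_changes`)."""
    if matrix.n_samples < 8:
        raise ValueError("fold change needs at least 8 samples (first and last four)")
    r = np.power(10.0, matrix.gene_row(gene_id))
    return float(np.nanmean(r[-4:]) / np.nanmean(r[:4]))


@dataclass
class DifferentialResult:
    """Per-gene differential statistics plus the selection threshold used."""

    table: pd.DataFrame  # columns: t, p, fold_change, significant
    n_perm: int
    full_enumeration: bool
    alpha: float
    max_false_prop: float
    t_threshold: float  # |t| cutoff chosen by the false-significant control
    false_prop_est: float

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistics (b minus a); NaN where both groups are constant."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / denom
    return t


def permutation_differential(
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_ids: list[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    max_false_prop: float = 0.01,
    seed: int = 0,
) -> DifferentialResult:
    """Permutation t test between two groups of logged expression columns.

    Parameters
    ----------
    group_a, group_b:
        ``(n_genes, n_a)`` and ``(n_genes, n_b)`` arrays of logged values.
    n_perm:
        Number of label permutations.  When the total number of
        arrangements C(n_a+n_b, n_a) is <= ``n_perm`` they are enumerated
        exhaustively; otherwise ``n_perm`` random splits are drawn and the
        identity permutation is included via the (1 + count)/(n_perm + 1)
        convention, so p is never 0.
    alpha, max_false_prop:
        Overall critical p threshold and the bound on the permutation-
        estimated proportion of false significant genes.

    Fold change is reported on the non-logged scale (group B over group A).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("groups must be 2-D with matching gene counts")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples in each group")
    n_genes = a.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]

    t_obs = _welch_t(a, b)
    constant = ~np.isfinite(t_obs)
    if np.any(constant):
        log.warning("%d genes constant in both groups; their p set to 1", int(constant.sum()))
    abs_obs = np.abs(np.where(constant, 0.0, t_obs))

    pooled = np.concatenate([a, b], axis=1)
    n = na + nb
    total = comb(n, na)
    full = total <= max(n_perm, 100)
    if full:
        splits = [np.array(c) for c in combinations(range(n), na)]
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 for sampled permutations")
        rng = np.random.default_rng(seed)
        splits = [rng.permutation(n)[:na] for _ in range(n_perm)]
    abs_perm = np.empty((n_genes, len(splits)))
    mask = np.zeros(n, dtype=bool)
    for j, idx_a in enumerate(splits):
        mask[:] = False
        mask[idx_a] = True
        tp = _welch_t(pooled[:, mask], pooled[:, ~mask])
        abs_perm[:, j] = np.abs(np.nan_to_num(tp, nan=0.0))

    ge = abs_perm >= abs_obs[:, None]
    if full:
        p = ge.sum(axis=1) / len(splits)
    else:
        p = (1.0 + ge.sum(axis=1)) / (len(splits) + 1.0)
    p = np.where(constant, 1.0, p)

    # False-significant-proportion control: among |t| thresholds attained by
    # genes with p <= alpha, keep the loosest one whose median permutation
    # exceedance count, relative to the observed count, stays within bound.
    candidates = np.sort(np.unique(abs_obs[(p <= alpha) & ~constant]))
    t_threshold = np.inf
    false_prop = float("nan")
    sorted_perm = np.sort(abs_perm, axis=0)  # per permutation, ascending
    for c in candidates:
        r = int(np.sum(abs_obs >= c))
        exceed = abs_perm.shape[0] - np.array(
            [np.searchsorted(sorted_perm[:, j], c, side="left") for j in range(abs_perm.shape[1])]
        )
        v = float(np.median(exceed))
        if r > 0 and v / r <= max_false_prop:
            t_threshold = float(c)
            false_prop = v / r
            break
    significant = (p <= alpha) & (abs_obs >= t_threshold) & ~constant

    with np.errstate(invalid="ignore"):
        fc = np.power(10.0, b).mean(axis=1) / np.power(10.0, a).mean(axis=1)
    table = pd.DataFrame(
        {"t": t_obs, "p": p, "fold_change": fc, "significant": significant},
        index=pd.Index(gene_ids, name="gene"),
    )
    return DifferentialResult(
        table=table,
        n_perm=len(splits),
        full_enumeration=full,
        alpha=alpha,
        max_false_prop=max_false_prop,
        t_threshold=t_threshold,
        false_prop_est=false_prop,
    )


def endpoint_change_test(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene change between the first and last four growth-ordered samples.

    A Welch t test on the stored log10 ratios compares each gene's first
    four against its last four samples; flags are set after
    Benjamini-Hochberg control at rate ``fdr`` (and p <= alpha).  The
    returned frame has columns ``fold_change``, ``t``, ``p``, ``q`` and
    ``flag`` (0/1), indexed by gene.
    """
    if matrix.n_samples < 8:
        raise ValueError("endpoint test needs at least 8 samples")
    x = matrix.log10_ratio
    first, last = x[:, :4], x[:, -4:]
    t = _welch_t(first, last)
    constant = ~np.isfinite(t)
    if np.any(constant):
        log.warning("%d genes constant at both ends; their p set to 1", int(constant.sum()))
    df_num = (first.var(axis=1, ddof=1) / 4 + last.var(axis=1, ddof=1) / 4) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        df_den = (first.var(axis=1, ddof=1) / 4) ** 2 / 3 + (last.var(axis=1, ddof=1) / 4) ** 2 / 3
        df = df_num / df_den
    p = np.where(constant, 1.0, 2.0 * stats.t.sf(np.abs(np.where(constant, 0, t)), np.where(constant, 1, df)))
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    flag = (reject & (p <= alpha)).astype(int)
    return pd.DataFrame(
        {
            "fold_change": fold_changes(matrix).to_numpy(),
            "t": t,
            "p": p,
            "q": q,
            "flag": flag,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
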