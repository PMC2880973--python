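"""Lambda significance statistics and the temporal-persistence filter.

Two-color ratio arrays measure, for every gene and harvest, the ratio of
transcript abundance between a test sample and a common reference.  The
significance of a change at one condition is summarized by a generalized
likelihood-ratio statistic lambda computed under a global two-parameter
error model fitted once across all genes:

    x = mu * (1 + eps_mult) + eps_add,
    eps_add ~ N(0, sigma_add^2),  eps_mult ~ N(0, sigma_mult^2),

so a non-logged ratio observation x around true ratio mu has variance
v(mu) = sigma_add^2 + mu^2 sigma_mult^2.  For one gene/condition with m
replicate ratio observations and sample mean xbar, the statistic is the
likelihood ratio for H0: mu = 1 (no change) against a free mean, with the
variance evaluated at the estimated mean and treated as known (a plug-in
convention, in the spirit of global-error-model array statistics):

    lambda = m * (xbar - 1)^2 / (sigma_add^2 + xbar^2 sigma_mult^2).

lambda is zero exactly when the replicate ratios average to 1, increases
with the departure of the mean from 1, and is asymptotically chi^2(1) under
the null when the error model holds.

A gene is called significant over the growth curve when lambda stays above
a threshold for a run of k consecutive growth-ordered data points,
duplicate cultures included (the duplicate columns are interleaved in OD
order, so a run of 4 typically spans 2 timepoints x 2 cultures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import ExpressionMatrix

__all__ = [
    "ErrorParams",
    "estimate_error_params",
    "lambda_statistic",
    "lambda_matrix",
    "persistent_significant_set",
    "threshold_sweep",
]

log = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class ErrorParams:
    """Fitted additive/multiplicative noise scales of the ratio error model."""

    sigma_add: float
    sigma_mult: float
    converged: bool = True
    n_genes: int = 0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.sigma_mult < 0:
            raise ValueError("noise scales must be >= 0")

    @property
    def degenerate(self) -> bool:
        """Both scales at the lower bound — fit on (near) noise-free data."""
        return self.sigma_add <= _SIGMA_FLOOR and self.sigma_mult <= _SIGMA_FLOOR

    def variance(self, mu: np.ndarray | float) -> np.ndarray | float:
        return self.sigma_add**2 + np.square(mu) * self.sigma_mult**2


def estimate_error_params(
    replicated_obs: np.ndarray,
    max_iter: int = 500,
) -> ErrorParams:
    """Fit (sigma_add, sigma_mult) by maximum likelihood on replicate scatter.

    Parameters
    ----------
    replicated_obs:
        ``(n_genes, n_replicates)`` array of non-logged ratio observations;
        NaN marks missing replicates.  Each gene's true ratio is treated as
        a nuisance mean estimated by the replicate average; the two noise
        scales are then fitted to the within-gene residual sums of squares,
        whose variance v(mu) = sigma_add^2 + mu^2 sigma_mult^2 varies with
        the gene mean and thereby separates the two components.

    Raises
    ------
    ValueError
        If fewer than 100 genes carry >= 2 replicates, or the optimizer
        fails to converge within ``max_iter`` iterations (the error message
        carries the last iterate).
    """
    x = np.asarray(replicated_obs, dtype=float)
    if x.ndim != 2:
        raise ValueError("replicated_obs must be 2-D (genes x replicates)")
    finite = np.isfinite(x)
    m = finite.sum(axis=1)
    keep = m >= 2
    if int(keep.sum()) < 100:
        raise ValueError(
            f"need >= 100 genes with >= 2 replicate observations, got {int(keep.sum())}"
        )
    x = np.where(finite, x, 0.0)[keep]
    finite = finite[keep]
    m = m[keep].astype(float)
    mean = x.sum(axis=1) / m
    resid = np.where(finite, x - mean[:, None], 0.0)
    ss = np.sum(resid * resid, axis=1)
    df = m - 1.0
    mu2 = mean * mean

    def nll(params: np.ndarray) -> float:
        sa, sm = params
        v = sa * sa + mu2 * sm * sm
        return float(np.sum(0.5 * df * np.log(v) + ss / (2.0 * v)))

    res = optimize.minimize(
        nll,
        x0=np.array([0.1, 0.1]),
        method="L-BFGS-B",
        bounds=[(_SIGMA_FLOOR, None), (_SIGMA_FLOOR, None)],
        options={"maxiter": max_iter},
    )
    if not res.success and res.status != 1:  # status 1 = iteration cap
        raise ValueError(f"error-model fit failed to converge: {res.message}; last iterate {res.x}")
    if not res.success:
        raise ValueError(f"error-model fit hit iteration cap {max_iter}; last iterate {res.x}")
    sa, sm = (float(v) for v in res.x)
    params = ErrorParams(sa, sm, converged=True, n_genes=int(keep.sum()), loglik=-float(res.fun))
    if params.degenerate:
        log.warning("error-model fit degenerate: both noise scales at the lower bound")
    return params


def lambda_statistic(gene_obs: np.ndarray, params: ErrorParams) -> float:
    """Likelihood-ratio lambda for one gene at one condition.

    ``gene_obs`` are the replicate non-logged ratio observations (>= 2).
    Returns 0 exactly when the replicate mean is 1.
    """
    if params is None:
        raise ValueError("error-model parameters are required")
    obs = np.asarray(gene_obs, dtype=float)
    obs = obs[np.isfinite(obs)]
    if obs.size < 2:
        raise ValueError("need >= 2 replicate observations for lambda")
    xbar = float(np.mean(obs))
    v = params.variance(xbar)
    if v <= 0:
        raise ValueError("error model gives non-positive variance; refit on noisy data")
    return float(obs.size * (xbar - 1.0) ** 2 / v)


def lambda_matrix(matrix: ExpressionMatrix, params: ErrorParams) -> np.ndarray:
    """Compute the genes x samples lambda matrix of an expression matrix.

    Replicate observations for one condition are the samples sharing
    (strain, sample_index) — duplicate cultures and dye orientations of one
    harvest.  The per-condition lambda is broadcast to each member column so
    the result aligns with the sample axis; conditions with fewer than two
    non-missing replicates yield NaN.
    """
    ratios = np.power(10.0, matrix.log10_ratio)
    lam = np.full(matrix.shape, np.nan)
    groups: dict[tuple[str, int], list[int]] = {}
    for j, s in enumerate(matrix.samples):
        groups.setdefault((s.strain, s.sample_index), []).append(j)
    for cols in groups.values():
        block = ratios[:, cols]
        finite = np.isfinite(block)
        m = finite.sum(axis=1).astype(float)
        ok = m >= 2
        xbar = np.where(ok, np.nansum(np.where(finite, block, 0.0), axis=1) / np.maximum(m, 1), np.nan)
        v = params.variance(xbar)
        with np.errstate(invalid="ignore"):
            val = m * (xbar - 1.0) ** 2 / v
        val = np.where(ok, val, np.nan)
        for c in cols:
            lam[:, c] = val
    return lam


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Per-row maximum run length of True in a boolean matrix."""
    best = np.zeros(above.shape[0], dtype=int)
    cur = np.zeros(above.shape[0], dtype=int)
    for j in range(above.shape[1]):
        cur = np.where(above[:, j], cur + 1, 0)
        best = np.maximum(best, cur)
    return best


def persistent_significant_set(
    lam: np.ndarray,
    gene_ids: list[str] | None = None,
    lambda0: float = 15.0,
    k: int = 4,
    column_strains: list[str] | None = None,
) -> set:
    """Genes whose lambda exceeds ``lambda0`` over >= k consecutive conditions.

    The inequality is strict (lambda > lambda0) and missing lambda values
    break a run.  Conditions are scanned in their stored (growth) order;
    when ``column_strains`` is given, runs are scanned within each strain's
    block of columns separately and the significant sets are united.
    Returns gene ids if ``gene_ids`` is given, else row indices.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.ndim != 2:
        raise ValueError("lambda matrix must be 2-D")
    if k < 1:
        raise ValueError("run length k must be >= 1")
    if column_strains is None:
        column_strains = ["_all_"] * lam.shape[1]
    if len(column_strains) != lam.shape[1]:
        raise ValueError("column_strains length must equal number of conditions")

    hit = np.zeros(lam.shape[0], dtype=bool)
    for strain in dict.fromkeys(column_strains):
        cols = [j for j, s in enumerate(column_strains) if s == strain]
        if k > len(cols):
            raise ValueError(f"run length k={k} exceeds the {len(cols)} conditions of {strain!r}")
        block = lam[:, cols]
        above = np.isfinite(block) & (block > lambda0)
        hit |= _max_run_lengths(above) >= k
    idx = np.nonzero(hit)[0]
    if gene_ids is None:
        return set(idx.tolist())
    return {gene_ids[i] for i in idx}


def persistent_significant_genes(
    matrix: ExpressionMatrix, lambda0: float = 15.0, k: int = 4
) -> set[str]:
    """Persistence filter applied to an ExpressionMatrix's stored lambda."""
    if matrix.lam is None:
        raise ValueError("matrix carries no lambda values")
    return persistent_significant_set(
        matrix.lam,
        gene_ids=matrix.gene_ids,
        lambda0=lambda0,
        k=k,
        column_strains=[s.strain for s in matrix.samples],
    )


def threshold_sweep(
    lam: np.ndarray,
    lambda0_list: list[float],
    k_list: list[int],
    n_total_genes: int,
    column_strains: list[str] | None = None,
) -> pd.DataFrame:
    """Gene counts passing the persistence filter over a threshold grid.

    Returns one row per (lambda0, k) pair with columns ``lambda0``, ``k``,
    ``gene_count`` and ``fraction`` (of ``n_total_genes``).  Counts are
    checked to be non-increasing in lambda0 at fixed k and non-increasing in
    k at fixed lambda0; a violation indicates an internal error.
    """
    if not lambda0_list or not k_list:
        raise ValueError("lambda0_list and k_list must be non-empty")
    lam = np.asarray(lam, dtype=float)
    if n_total_genes < lam.shape[0]:
        raise ValueError("n_total_genes smaller than the observed gene count")
    rows = []
    for lambda0 in lambda0_list:
        for k in k_list:
            count = len(
                persistent_significant_set(lam, None, lambda0, k, column_strains)
            )
            rows.append(
                {
                    "lambda0": float(lambda0),
                    "k": int(k),
                    "gene_count": count,
                    "fraction": count / n_total_genes,
                }
            )
    table = pd.DataFrame(rows)
    for k in k_list:
        sub = table[table["k"] == k].sort_values("lambda0")
        if np.any(np.diff(sub["gene_count"].to_numpy()) > 0):
            raise AssertionError("internal error: counts increased with lambda0")
    for lambda0 in lambda0_list:
        sub = table[table["lambda0"] == float(lambda0)].sort_values("k")
        if np.any(np.diff(sub["gene_count"].to_numpy()) > 0):
            raise AssertionError("internal error: counts increased with run length k")
    return table
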