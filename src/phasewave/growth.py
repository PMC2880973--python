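"""Growth-curve quantification and phase annotation.

Batch cultures pass through four operationally defined phases: EARLY lag
growth, rapid EXPONENTIAL growth, the TRANSITION out of exponential growth,
and STATIONARY phase.  Because published growth narratives rarely give
operational boundaries, the partition used here is defined relative to the
specific growth rate mu(t) = d ln(OD)/dt estimated by finite differences:

* EXPONENTIAL — the contiguous block of timepoints around the mu maximum
  where mu >= f_exp * mu_max (default f_exp = 0.5);
* EARLY       — every timepoint before that block;
* STATIONARY  — the trailing contiguous block where mu <= f_stat * mu_max
  (default f_stat = 0.1);
* TRANSITION  — everything between EXPONENTIAL and STATIONARY.

Both fractions are configurable and recorded in the annotation so that
downstream outputs carry the convention that produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GrowthCurve

__all__ = [
    "PHASES",
    "GrowthFit",
    "PhaseAnnotation",
    "replicate_rmsd",
    "estimate_growth_rates",
    "annotate_phases",
]

PHASES = ("EARLY", "EXPONENTIAL", "TRANSITION", "STATIONARY")
_PHASE_RANK = {p: i for i, p in enumerate(PHASES)}


@dataclass(frozen=True)
class GrowthFit:
    """Finite-difference growth-rate estimates for one curve.

    ``mu`` holds the per-timepoint specific growth rate in 1/h (central
    differences of ln OD, one-sided at the ends).  ``doubling_time`` is
    ln 2 / mu_max in hours, NaN when the curve never grows (mu_max <= 0).
    """

    mu: np.ndarray
    mu_max: float
    t_mu_max: float
    doubling_time: float

    @property
    def has_growth(self) -> bool:
        return self.mu_max > 0 and np.isfinite(self.doubling_time)


@dataclass(frozen=True)
class PhaseAnnotation:
    """Per-timepoint growth-phase labels for one sampling design.

    Labels form contiguous blocks in the order EARLY -> EXPONENTIAL ->
    TRANSITION -> STATIONARY (empty blocks allowed).  ``boundaries`` maps
    each non-empty phase to its (start_time, end_time) in hours.
    """

    labels: tuple[str, ...]
    times: np.ndarray
    f_exp: float
    f_stat: float
    boundaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = [_PHASE_RANK[l] for l in self.labels]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("phase labels must be ordered EARLY->EXPONENTIAL->TRANSITION->STATIONARY")

    def __len__(self) -> int:
        return len(self.labels)

    def label_for_index(self, sample_index: int) -> str:
        return self.labels[sample_index]

    def indices_of(self, phase: str) -> list[int]:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        return [i for i, l in enumerate(self.labels) if l == phase]


def replicate_rmsd(a: GrowthCurve, b: GrowthCurve, time_atol: float = 1e-6) -> float:
    """Root-mean-square distance between two replicate growth curves.

    Only timepoints that match between the two curves (within ``time_atol``
    hours) are compared; interpolation is deliberately not performed because
    replicate cultures of one experiment share a sampling design.
    """
    ia, ib = [], []
    j = 0
    for i, t in enumerate(a.time_h):
        while j < len(b) and b.time_h[j] < t - time_atol:
            j += 1
        if j < len(b) and abs(b.time_h[j] - t) <= time_atol:
            ia.append(i)
            ib.append(j)
            j += 1
    if not ia:
        raise ValueError("growth curves share no matched timepoints")
    d = a.od600[ia] - b.od600[ib]
    return float(np.sqrt(np.mean(d * d)))


def estimate_growth_rates(curve: GrowthCurve, smooth_window: int = 1) -> GrowthFit:
    """Estimate the specific growth rate mu(t) = d ln(OD)/dt per timepoint.

    Central finite differences on ln OD are exact for pure exponential
    growth; one-sided differences are used at the ends.  ``smooth_window``
    (odd) optionally applies a moving average to ln OD before
    differentiation for noisy curves; the default applies no smoothing.
    """
    if len(curve) < 4:
        raise ValueError("at least 4 points are required to estimate growth rates")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    t = curve.time_h
    ln_od = np.log(curve.od600)
    if smooth_window > 1:
        k = smooth_window // 2
        padded = np.pad(ln_od, k, mode="edge")
        ln_od = np.convolve(padded, np.ones(smooth_window) / smooth_window, mode="valid")
    mu = np.empty_like(ln_od)
    mu[1:-1] = (ln_od[2:] - ln_od[:-2]) / (t[2:] - t[:-2])
    mu[0] = (ln_od[1] - ln_od[0]) / (t[1] - t[0])
    mu[-1] = (ln_od[-1] - ln_od[-2]) / (t[-1] - t[-2])
    i_max = int(np.argmax(mu))
    mu_max = float(mu[i_max])
    doubling = float(np.log(2.0) / mu_max) if mu_max > 0 else float("nan")
    return GrowthFit(mu=mu, mu_max=mu_max, t_mu_max=float(t[i_max]), doubling_time=doubling)


def annotate_phases(
    fit: GrowthFit,
    curve: GrowthCurve,
    f_exp: float = 0.5,
    f_stat: float = 0.1,
) -> PhaseAnnotation:
    """Partition a growth curve's timepoints into the four growth phases.

    See the module docstring for the operational definitions.  Raises when
    the curve shows no growth (mu_max = 0), since no exponential phase can
    then be located.
    """
    if not (0.0 < f_stat < f_exp < 1.0):
        raise ValueError("require 0 < f_stat < f_exp < 1")
    if len(fit.mu) != len(curve):
        raise ValueError("fit does not match curve length")
    if fit.mu_max <= 0:
        raise ValueError("no exponential phase detected (mu_max = 0)")

    mu = fit.mu
    n = len(mu)
    i_max = int(np.argmax(mu))
    # EXPONENTIAL: grow the block outward from the mu maximum.
    lo = i_max
    while lo > 0 and mu[lo - 1] >= f_exp * fit.mu_max:
        lo -= 1
    hi = i_max
    while hi < n - 1 and mu[hi + 1] >= f_exp * fit.mu_max:
        hi += 1
    labels = ["EARLY"] * lo + ["EXPONENTIAL"] * (hi - lo + 1) + ["TRANSITION"] * (n - hi - 1)
    # STATIONARY: trailing block of low mu, never eating into EXPONENTIAL.
    j = n - 1
    while j > hi and mu[j] <= f_stat * fit.mu_max:
        labels[j] = "STATIONARY"
        j -= 1

    boundaries: dict[str, tuple[float, float]] = {}
    t = curve.time_h
    for phase in PHASES:
        idx = [i for i, l in enumerate(labels) if l == phase]
        if idx:
            boundaries[phase] = (float(t[idx[0]]), float(t[idx[-1]]))
    return PhaseAnnotation(
        labels=tuple(labels), times=t.copy(), f_exp=f_exp, f_stat=f_stat, boundaries=boundaries
    )
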