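"""Cell-shape metrics, circularity mixture models and the gas-vesicle index.

Fixed cells imaged by phase contrast are summarized per cell by area,
perimeter, circularity C = 4*pi*A/P^2 (1 for a disc, small for elongated
rods), axis lengths and mean pixel intensity.  At each growth timepoint the
distribution of circularities is modelled as a two-component Gaussian
mixture fitted by EM: component 1 (lower mean circularity) tracks rod
cells, component 2 spherical cells.  The mixture weight w2(t) traced over
the growth curve quantifies rod-to-sphere morphology shifts; the median of
per-cell mean pixel intensities serves as a robust proxy for gas-vesicle
content (vesicles scatter light and brighten cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .datatypes import GrowthCurve

__all__ = [
    "CellMeasurement",
    "MixtureFit",
    "MorphologyTrajectory",
    "shape_metrics",
    "fit_two_component_mixture",
    "population_trajectory",
    "gas_vesicle_index",
]

log = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-3
MIN_CELLS = 50  # minimum cells per timepoint for a mixture fit


@dataclass(frozen=True)
class CellMeasurement:
    """Shape and intensity summary of one segmented cell."""

    cell_id: str
    timepoint: int
    area: float
    perimeter: float
    circularity: float
    major_axis: float
    minor_axis: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise ValueError("area and perimeter must be > 0")
        if not (0 < self.circularity <= 1):
            raise ValueError("circularity must lie in (0, 1]")


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture of circularities (component 1 = rods).

    Components are ordered so mu1 <= mu2.  ``loglik_trace`` records the
    observed-data log-likelihood after every EM iteration; EM guarantees it
    is non-decreasing.  ``overlap`` flags fits whose components are closer
    than the wider of the two sds and are therefore weakly identified.
    """

    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    n_cells: int
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def overlap(self) -> bool:
        return abs(self.mu2 - self.mu1) < max(self.sigma1, self.sigma2)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        d1 = self.w1 * _normal_pdf(x, self.mu1, self.sigma1)
        d2 = self.w2 * _normal_pdf(x, self.mu2, self.sigma2)
        return d2 / (d1 + d2)


@dataclass
class MorphologyTrajectory:
    """Per-timepoint mixture fits aligned to the growth curve."""

    timepoints: list[int]
    fits: list[MixtureFit]
    od600: list[float]

    def w2_series(self) -> np.ndarray:
        return np.array([f.w2 for f in self.fits])

    def mu1_series(self) -> np.ndarray:
        return np.array([f.mu1 for f in self.fits])

    def mu2_series(self) -> np.ndarray:
        return np.array([f.mu2 for f in self.fits])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timepoint": self.timepoints,
                "od600": self.od600,
                "w1": [f.w1 for f in self.fits],
                "w2": [f.w2 for f in self.fits],
                "mu1": [f.mu1 for f in self.fits],
                "mu2": [f.mu2 for f in self.fits],
                "sigma1": [f.sigma1 for f in self.fits],
                "sigma2": [f.sigma2 for f in self.fits],
                "n_cells": [f.n_cells for f in self.fits],
                "converged": [f.converged for f in self.fits],
            }
        )


def shape_metrics(
    mask: np.ndarray,
    intensity: np.ndarray | None = None,
    cell_id: str = "cell",
    timepoint: int = 0,
) -> CellMeasurement:
    """Shape metrics of a single binary cell mask.

    The mask must contain exactly one 8-connected component of >= 20
    pixels.  Perimeter uses a corner-corrected crack-length estimator so a
    rasterized disc lands near C = 1 rather than overshooting; circularity
    is clamped to (0, 1].  Axis lengths come from the second central
    moments (equivalent-ellipse convention).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    labeled, n_comp = measure.label(mask, connectivity=2, return_num=True)
    if n_comp != 1:
        raise ValueError(f"mask must contain exactly one connected component, found {n_comp}")
    if mask.sum() < 20:
        raise ValueError("component smaller than 20 pixels")
    props = measure.regionprops(labeled, intensity_image=intensity)[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    circ = min(1.0, 4.0 * np.pi * area / perimeter**2)
    mean_int = float(props.intensity_mean) if intensity is not None else float("nan")
    return CellMeasurement(
        cell_id=cell_id,
        timepoint=timepoint,
        area=area,
        perimeter=perimeter,
        circularity=circ,
        major_axis=float(props.axis_major_length),
        minor_axis=float(props.axis_minor_length),
        mean_intensity=mean_int,
    )


def _normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


def fit_two_component_mixture(
    circularities: np.ndarray,
    init: tuple[float, float, float, float, float] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    allow_small: bool = False,
) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to circularity values.

    Parameters
    ----------
    circularities:
        Values in (0, 1]; at least ``MIN_CELLS`` unless ``allow_small``.
    init:
        Optional warm start ``(w2, mu1, mu2, sigma1, sigma2)``.  The default
        initialization splits the sample at its 40th percentile (rod-heavy
        prior) and uses the two halves' moments.
    tol:
        Convergence when the log-likelihood gain per iteration drops below
        ``tol``.

    The fit is Gaussian on the raw values with a sd floor of 1e-3 against
    component collapse; components are returned ordered mu1 <= mu2.
    Non-convergence returns the last iterate with ``converged=False`` and a
    warning rather than raising.
    """
    x = np.asarray(circularities, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < MIN_CELLS:
        if not allow_small:
            raise ValueError(f"need >= {MIN_CELLS} cells for a mixture fit, got {n}")
        log.warning("mixture fit on only %d cells (< %d)", n, MIN_CELLS)
    if n < 4:
        raise ValueError("too few cells for any mixture fit")
    if np.ptp(x) == 0:
        raise ValueError("all circularity values identical; mixture not identifiable")

    if init is None:
        q = np.quantile(x, 0.4)
        lower, upper = x[x <= q], x[x > q]
        if lower.size < 2 or upper.size < 2:
            med = np.median(x)
            lower, upper = x[x <= med], x[x > med]
        w2 = upper.size / n
        mu1, mu2 = float(np.mean(lower)), float(np.mean(upper))
        s1 = max(float(np.std(lower)), _SIGMA_FLOOR)
        s2 = max(float(np.std(upper)), _SIGMA_FLOOR)
    else:
        w2, mu1, mu2, s1, s2 = (float(v) for v in init)
        s1, s2 = max(s1, _SIGMA_FLOOR), max(s2, _SIGMA_FLOOR)
    w2 = min(max(w2, 1e-6), 1 - 1e-6)
    w1 = 1.0 - w2

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d1 = w1 * _normal_pdf(x, mu1, s1)
        d2 = w2 * _normal_pdf(x, mu2, s2)
        total = d1 + d2
        total = np.maximum(total, 1e-300)
        ll = float(np.sum(np.log(total)))
        r2 = d2 / total
        r1 = 1.0 - r2
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M step
        n1, n2 = float(np.sum(r1)), float(np.sum(r2))
        n1, n2 = max(n1, 1e-12), max(n2, 1e-12)
        w1, w2 = n1 / n, n2 / n
        mu1 = float(np.sum(r1 * x) / n1)
        mu2 = float(np.sum(r2 * x) / n2)
        s1 = max(float(np.sqrt(np.sum(r1 * (x - mu1) ** 2) / n1)), _SIGMA_FLOOR)
        s2 = max(float(np.sqrt(np.sum(r2 * (x - mu2) ** 2) / n2)), _SIGMA_FLOOR)
    if not converged:
        log.warning("mixture EM did not converge in %d iterations", max_iter)
    if mu1 > mu2:
        w1, w2 = w2, w1
        mu1, mu2 = mu2, mu1
        s1, s2 = s2, s1
    fit = MixtureFit(
        w1=w1, w2=w2, mu1=mu1, mu2=mu2, sigma1=s1, sigma2=s2,
        loglik=trace[-1], n_iter=it, converged=converged, n_cells=n,
        loglik_trace=trace,
    )
    if fit.overlap:
        log.info("mixture components overlap (|mu2-mu1| < max sd); weakly identified")
    return fit


def population_trajectory(
    cells: pd.DataFrame,
    growth: GrowthCurve,
) -> MorphologyTrajectory:
    """Per-timepoint mixture fits over a growth curve.

    ``cells`` must have columns ``timepoint`` and ``circularity`` (the
    morphology table layout).  Timepoints index into the growth curve; each
    needs >= 50 cells.  Fits are warm-started from the previous timepoint
    to stabilize the component labelling along the trajectory.
    """
    required = {"timepoint", "circularity"}
    if not required <= set(cells.columns):
        raise ValueError(f"cells table must have columns {sorted(required)}")
    timepoints = sorted(int(t) for t in cells["timepoint"].unique())
    for t in timepoints:
        if t < 0 or t >= len(growth):
            raise ValueError(f"timepoint {t} missing from the growth curve")
    fits: list[MixtureFit] = []
    warm: tuple[float, float, float, float, float] | None = None
    for t in timepoints:
        x = cells.loc[cells["timepoint"] == t, "circularity"].to_numpy()
        fit = fit_two_component_mixture(x, init=warm)
        fits.append(fit)
        warm = (fit.w2, fit.mu1, fit.mu2, fit.sigma1, fit.sigma2)
    return MorphologyTrajectory(
        timepoints=timepoints,
        fits=fits,
        od600=[float(growth.od600[t]) for t in timepoints],
    )


def gas_vesicle_index(intensities: np.ndarray) -> float:
    """Median of per-cell mean pixel intensities at one timepoint.

    The median is robust to the bright outliers produced by free-floating
    vesicle clusters.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no intensity values")
    return float(np.median(x))
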