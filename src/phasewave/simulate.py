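"""Synthetic study generator with recoverable ground truth.

Every simulator here is a pure function of its parameters and seed.  The
generated data emulate a batch-culture growth study of a halophilic
archaeon profiled by two-color ratio arrays:

* growth curves follow a Baranyi-style lag/logistic trajectory with an
  optional delayed secondary OD rise (free gas vesicles released late in
  the experiment scatter light and raise the apparent OD);
* expression matrices plant five temporal archetypes plus null genes as
  piecewise-constant log10-ratio templates over the growth phases, observed
  through additive-plus-multiplicative Gaussian noise on the non-logged
  ratio scale (the same error-model family the significance module fits),
  in duplicate cultures with one dye-flip per harvest;
* morphology tables draw per-cell circularities from a planted
  two-component mixture (rods vs spheres), truncated to (0, 1] by
  resampling;
* metabolite tables plant concordant features whose three-phase abundance
  profile follows a gene-group shape at a requested early/stationary fold,
  among flat background features.

The planted truth is returned alongside each table so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenomeAnnotation, GrowthCurve, SampleMeta
from .growth import PhaseAnnotation
from . import significance

__all__ = [
    "ARCHETYPE_TEMPLATES",
    "SimulationTruth",
    "default_phase_labels",
    "make_phase_annotation",
    "simulate_growth_curve",
    "simulate_expression",
    "simulate_morphology",
    "simulate_metabolites",
    "simulate_annotation",
    "simulate_study",
    "StudyBundle",
]

# Piecewise-constant template coefficients (EARLY, EXPONENTIAL, TRANSITION,
# STATIONARY) in units of the effect size, per archetype.  Pulses are
# confined to one segment; the two dominant classes are step-like.
ARCHETYPE_TEMPLATES: dict[str, tuple[float, float, float, float]] = {
    "EXP_HIGH": (1.0, 1.0, 0.0, -1.0),
    "STAT_HIGH": (-1.0, -1.0, 0.0, 1.0),
    "TRANSIENT_UP_EXP": (0.0, 1.0, 0.0, 0.0),
    "TRANSIENT_DOWN_EXP": (0.0, -1.0, 0.0, 0.0),
    "TRANSIENT_UP_TRANSITION": (0.0, 0.0, 1.0, 0.0),
    "NULL": (0.0, 0.0, 0.0, 0.0),
}

_PHASE_POS = {"EARLY": 0, "EXPONENTIAL": 1, "TRANSITION": 2, "STATIONARY": 3}

#: Default class sizes for a full-scale simulated genome, mirroring the
#: reported memberships of the five temporal classes (451 exponential-high,
#: 772 stationary-high, 10 / 4 / 18 transient genes) out of ~2400 genes.
DEFAULT_CLASS_SIZES = {
    "EXP_HIGH": 451,
    "STAT_HIGH": 772,
    "TRANSIENT_UP_EXP": 10,
    "TRANSIENT_DOWN_EXP": 4,
    "TRANSIENT_UP_TRANSITION": 18,
    "NULL": 1145,
}


@dataclass
class SimulationTruth:
    """Planted ground truth of a simulation."""

    seed: int
    archetype_of: dict[str, str] | None = None
    sigma_add: float = float("nan")
    sigma_mult: float = float("nan")
    mixture_params: list[tuple[float, float, float, float, float]] | None = None
    concordant_features: list[str] | None = None
    metabolite_profile: np.ndarray | None = None
    strain_diff_genes: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mixture_params is not None:
            for w2, mu1, mu2, s1, s2 in self.mixture_params:
                if not (0.0 <= w2 <= 1.0):
                    raise ValueError("mixture weight w2 must lie in [0, 1]")
                if mu1 > mu2:
                    raise ValueError("mixture means must satisfy mu1 <= mu2")
                if s1 < 0 or s2 < 0:
                    raise ValueError("mixture sds must be >= 0")

    def non_null_genes(self) -> set[str]:
        if self.archetype_of is None:
            return set()
        return {g for g, a in self.archetype_of.items() if a != "NULL"}


def default_phase_labels(n_points: int) -> tuple[str, ...]:
    """Phase labels of the default sampling design for ``n_points`` harvests."""
    if n_points < 4:
        raise ValueError("need >= 4 sampling points to cover all phases")
    if n_points == 7:
        return ("EARLY", "EXPONENTIAL", "EXPONENTIAL", "EXPONENTIAL", "TRANSITION", "TRANSITION", "STATIONARY")
    if n_points == 6:
        return ("EARLY", "EXPONENTIAL", "EXPONENTIAL", "TRANSITION", "TRANSITION", "STATIONARY")
    # General case: proportional split E:X:T:S ~ 1:3:2:1 with every phase
    # represented at least once.
    weights = np.array([1.0, 3.0, 2.0, 1.0])
    counts = np.maximum(1, np.round(weights / weights.sum() * n_points).astype(int))
    while counts.sum() > n_points:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < n_points:
        counts[int(np.argmin(counts))] += 1
    labels: list[str] = []
    for phase, c in zip(("EARLY", "EXPONENTIAL", "TRANSITION", "STATIONARY"), counts):
        labels.extend([phase] * int(c))
    return tuple(labels)


def make_phase_annotation(
    labels: tuple[str, ...], times: np.ndarray | None = None
) -> PhaseAnnotation:
    """Wrap explicit phase labels into a :class:`PhaseAnnotation`."""
    n = len(labels)
    if times is None:
        times = np.linspace(0.0, 10.0 * (n - 1), n)
    return PhaseAnnotation(labels=tuple(labels), times=np.asarray(times, float), f_exp=0.5, f_stat=0.1)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    mu_max: float = 0.25,
    od0: float = 0.02,
    od_max: float = 1.0,
    secondary_rise: float = 0.0,
    n_points: int = 7,
    seed: int = 0,
    lag_h: float = 0.0,
    t_span: float | None = None,
    times: np.ndarray | None = None,
    noise_cv: float = 0.0,
    secondary_time: float | None = None,
    secondary_tau: float | None = None,
    strain: str = "NRC-1",
    replicate: str = "A",
) -> GrowthCurve:
    """Simulate an OD600 growth curve.

    The deterministic part is a Baranyi-Roberts trajectory: logistic growth
    at maximum specific rate ``mu_max`` toward carrying capacity ``od_max``,
    preceded by a lag of ``lag_h`` hours (``lag_h=0`` gives a plain
    logistic).  ``secondary_rise`` adds a delayed sigmoidal OD increase of
    that amplitude late in the curve.  ``noise_cv`` applies multiplicative
    lognormal measurement noise.
    """
    if mu_max <= 0:
        raise ValueError("mu_max must be > 0")
    if not (0 < od0 < od_max):
        raise ValueError("require 0 < od0 < od_max")
    if n_points < 4 and times is None:
        raise ValueError("n_points must be >= 4")
    if times is None:
        if t_span is None:
            # span: lag plus ~1.5x the time to traverse the logistic rise
            t_span = lag_h + 1.5 * np.log(od_max / od0) / mu_max + 10.0
        times = np.linspace(0.0, float(t_span), n_points)
    times = np.asarray(times, dtype=float)

    if lag_h > 0:
        q0 = 1.0 / np.expm1(mu_max * lag_h)
        a = times + np.log((np.exp(-mu_max * times) + q0) / (1.0 + q0)) / mu_max
    else:
        a = times
    ln_od = (
        np.log(od0)
        + mu_max * a
        - np.log1p((np.expm1(mu_max * a)) * od0 / od_max)
    )
    od = np.exp(ln_od)
    if secondary_rise > 0:
        t_sec = secondary_time if secondary_time is not None else 0.85 * times[-1]
        tau = secondary_tau if secondary_tau is not None else max(0.03 * times[-1], 1.0)
        od = od + secondary_rise / (1.0 + np.exp(-(times - t_sec) / tau))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        od = od * np.exp(rng.normal(0.0, noise_cv, od.shape))
    return GrowthCurve(strain=strain, replicate=replicate, time_h=times, od600=od)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _noisy_ratio(rng: np.random.Generator, mu: np.ndarray, sigma_add: float, sigma_mult: float) -> np.ndarray:
    """Draw x = mu (1 + eps_mult) + eps_add, resampled to stay positive."""
    x = mu * (1.0 + rng.normal(0.0, sigma_mult, mu.shape)) + rng.normal(0.0, sigma_add, mu.shape)
    for _ in range(100):
        bad = x <= 0
        if not bad.any():
            break
        x[bad] = mu[bad] * (1.0 + rng.normal(0.0, sigma_mult, int(bad.sum()))) + rng.normal(
            0.0, sigma_add, int(bad.sum())
        )
    np.clip(x, 1e-6, None, out=x)
    return x


def simulate_expression(
    n_per_class: dict[str, int],
    phases: PhaseAnnotation,
    effect: float = 1.0,
    sigma_add: float = 0.1,
    sigma_mult: float = 0.1,
    replicates: int = 2,
    dye_flip: bool = True,
    seed: int = 0,
    strain: str = "NRC-1",
    od600: np.ndarray | None = None,
    gene_prefix: str = "SYN",
    compute_lambda: bool = True,
    strain_shift: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a replicated dye-flip expression matrix with planted classes.

    ``n_per_class`` maps archetype names (see :data:`ARCHETYPE_TEMPLATES`)
    to gene counts.  Each gene's mean log10-ratio trajectory is its class
    template (piecewise constant over the phase labels of ``phases``)
    scaled by ``effect``; observations on the non-logged ratio scale carry
    additive (``sigma_add``) plus multiplicative (``sigma_mult``) Gaussian
    noise.  One replicate culture per harvest is flagged as dye-flipped
    (values are stored orientation-corrected).  Lambda values are computed
    from the simulated replicate structure via the significance module
    unless ``compute_lambda`` is false.

    ``strain_shift`` optionally adds a constant log10 offset to named genes
    at every harvest (used to plant strain-specific differences).
    """
    unknown = set(n_per_class) - set(ARCHETYPE_TEMPLATES)
    if unknown:
        raise ValueError(f"unknown archetype classes: {sorted(unknown)}")
    counts = {c: int(n_per_class.get(c, 0)) for c in ARCHETYPE_TEMPLATES}
    n_genes = sum(counts.values())
    if n_genes == 0:
        raise ValueError("zero genes requested in every class")
    if effect <= 0 and any(v > 0 for c, v in counts.items() if c != "NULL"):
        raise ValueError("effect must be > 0 when non-null classes are planted")
    if replicates < 1:
        raise ValueError("need >= 1 replicate culture")
    n_points = len(phases)
    if od600 is None:
        od600 = np.geomspace(0.05, 1.5, n_points)
    od600 = np.asarray(od600, dtype=float)
    if od600.size != n_points:
        raise ValueError("od600 must give one value per sampling point")

    rng = np.random.default_rng(seed)
    gene_ids: list[str] = []
    archetype_of: dict[str, str] = {}
    template_rows = []
    phase_pos = [_PHASE_POS[l] for l in phases.labels]
    i = 0
    for cls in ARCHETYPE_TEMPLATES:  # deterministic order
        coef = ARCHETYPE_TEMPLATES[cls]
        for _ in range(counts[cls]):
            g = f"{gene_prefix}{i:04d}"
            gene_ids.append(g)
            archetype_of[g] = cls
            template_rows.append([effect * coef[p] for p in phase_pos])
            i += 1
    template = np.array(template_rows)  # genes x points, log10 units
    if strain_shift:
        gidx = {g: r for r, g in enumerate(gene_ids)}
        for g, shift in strain_shift.items():
            template[gidx[g]] += shift

    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    rep_names = [chr(ord("A") + r) for r in range(replicates)]
    for pt in range(n_points):
        mu_ratio = np.power(10.0, template[:, pt])
        for r, rep in enumerate(rep_names):
            flip = dye_flip and (r % 2 == 1)
            x = _noisy_ratio(rng, mu_ratio, sigma_add, sigma_mult)
            columns.append(np.log10(x))
            samples.append(
                SampleMeta(strain=strain, replicate=rep, sample_index=pt, dye_flip=flip, od600=float(od600[pt]))
            )
    data = np.column_stack(columns)
    matrix = ExpressionMatrix(gene_ids, samples, data)
    if compute_lambda and replicates >= 2:
        ratios = np.power(10.0, matrix.log10_ratio)
        groups: dict[tuple[str, int], list[int]] = {}
        for j, s in enumerate(matrix.samples):
            groups.setdefault((s.strain, s.sample_index), []).append(j)
        stacked = np.vstack([ratios[:, cols] for cols in groups.values()])
        params = significance.estimate_error_params(stacked)
        matrix = matrix.with_lambda(significance.lambda_matrix(matrix, params))
    truth = SimulationTruth(
        seed=seed, archetype_of=archetype_of, sigma_add=sigma_add, sigma_mult=sigma_mult,
        strain_diff_genes=dict(strain_shift) if strain_shift else None,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Morphology tables
# ---------------------------------------------------------------------------

def _truncated_mixture_draw(
    rng: np.random.Generator,
    n: int,
    w2: float,
    mu1: float,
    mu2: float,
    s1: float,
    s2: float,
) -> tuple[np.ndarray, np.ndarray]:
    comp = rng.random(n) < w2
    mu = np.where(comp, mu2, mu1)
    sd = np.where(comp, s2, s1)
    x = rng.normal(mu, sd)
    for _ in range(1000):
        bad = (x <= 0) | (x > 1)
        if not bad.any():
            break
        x[bad] = rng.normal(mu[bad], sd[bad])
    else:
        raise RuntimeError("truncated mixture sampling failed to converge")
    return x, comp


def simulate_morphology(
    trajectory: list[tuple[float, float, float, float, float]],
    n_cells: int | list[int] = 500,
    seed: int = 0,
    base_intensity: float = 100.0,
    intensity_sd: float = 8.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a per-cell morphology table from planted mixtures.

    ``trajectory`` lists per-timepoint mixture parameters
    ``(w2, mu1, mu2, sigma1, sigma2)`` of the circularity distribution
    (component 2 = spherical cells).  Circularities are drawn from the
    two-component Gaussian mixture truncated to (0, 1] by resampling; the
    remaining columns are filled consistently — low circularity implies a
    high major/minor aspect ratio via the equivalent-ellipse relation.
    """
    if not trajectory:
        raise ValueError("trajectory must list at least one timepoint")
    for w2, mu1, mu2, s1, s2 in trajectory:
        if not (0.0 <= w2 <= 1.0):
            raise ValueError("mixture weight w2 must lie in [0, 1]")
        if not (0 < mu1 <= 1 and 0 < mu2 <= 1):
            raise ValueError("mixture means must lie in (0, 1]")
        if mu1 > mu2:
            raise ValueError("require mu1 <= mu2 (component 1 = rods)")
        if s1 <= 0 or s2 <= 0:
            raise ValueError("mixture sds must be > 0")
    n_tp = len(trajectory)
    if isinstance(n_cells, int):
        n_cells = [n_cells] * n_tp
    if len(n_cells) != n_tp or any(n < 1 for n in n_cells):
        raise ValueError("n_cells must give a positive count per timepoint")

    rng = np.random.default_rng(seed)
    rows = []
    for t, ((w2, mu1, mu2, s1, s2), n) in enumerate(zip(trajectory, n_cells)):
        circ, comp = _truncated_mixture_draw(rng, n, w2, mu1, mu2, s1, s2)
        area = rng.lognormal(np.log(400.0), 0.15, n)
        perimeter = np.sqrt(4.0 * np.pi * area / circ)
        aspect = 1.0 / circ  # monotone: rounder cells -> aspect near 1
        major = 2.0 * np.sqrt(area * aspect / np.pi)
        minor = major / aspect
        intensity = rng.normal(base_intensity, intensity_sd, n)
        for c in range(n):
            rows.append(
                {
                    "cell_id": f"t{t}c{c:04d}",
                    "timepoint": t,
                    "area": area[c],
                    "perimeter": perimeter[c],
                    "circularity": circ[c],
                    "major_axis": major[c],
                    "minor_axis": minor[c],
                    "mean_intensity": intensity[c],
                    "component": int(comp[c]) + 1,
                }
            )
    table = pd.DataFrame(rows)
    truth = SimulationTruth(seed=seed, mixture_params=[tuple(map(float, p)) for p in trajectory])
    return table, truth


# ---------------------------------------------------------------------------
# Metabolite tables
# ---------------------------------------------------------------------------

def simulate_metabolites(
    n_features: int = 150,
    n_concordant: int = 10,
    gene_group_profile: tuple[float, float, float] = (1.0, 0.3, 1.2),
    fold: float = 4.0,
    noise_cv: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    base_abundance: float = 1000.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a metabolite feature table with planted concordant features.

    Concordant features follow ``gene_group_profile`` (relative abundances
    at EARLY/EXPONENTIAL/STATIONARY) rescaled so the early-to-stationary
    ratio is exactly ``fold`` (in the direction the profile indicates, or
    upward when the profile is flat across those ends); background features
    are flat.  Replicate abundances carry multiplicative Gaussian noise of
    coefficient of variation ``noise_cv``.
    """
    if n_concordant > n_features:
        raise ValueError("n_concordant cannot exceed n_features")
    if replicates < 2:
        raise ValueError("need >= 2 replicates per phase")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    profile = np.asarray(gene_group_profile, dtype=float)
    if profile.size != 3 or np.any(profile <= 0):
        raise ValueError("gene_group_profile must be 3 positive values")

    m_e = base_abundance
    m_x = base_abundance * profile[1] / profile[0]
    m_s = base_abundance / fold if profile[2] < profile[0] else base_abundance * fold
    planted_means = np.array([m_e, m_x, m_s])

    rng = np.random.default_rng(seed)
    rows = []
    concordant_ids = [f"M{i:04d}" for i in range(n_concordant)]
    phases = ("EARLY", "EXPONENTIAL", "STATIONARY")
    for i in range(n_features):
        fid = f"M{i:04d}"
        mz = float(rng.uniform(85.0, 1200.0))
        rt = float(rng.uniform(1.0, 35.0))
        means = planted_means if i < n_concordant else np.full(3, base_abundance * rng.uniform(0.5, 2.0))
        for p, phase in enumerate(phases):
            for r in range(replicates):
                ab = means[p] * (1.0 + noise_cv * rng.standard_normal()) if noise_cv > 0 else means[p]
                rows.append(
                    {
                        "feature_id": fid,
                        "mz": mz,
                        "rt_min": rt,
                        "phase": phase,
                        "replicate": f"r{r + 1}",
                        "abundance": max(float(ab), 0.0),
                    }
                )
    table = pd.DataFrame(rows)
    sd = planted_means.std()
    truth = SimulationTruth(
        seed=seed,
        concordant_features=concordant_ids,
        metabolite_profile=(planted_means - planted_means.mean()) / sd if sd > 0 else None,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Genome annotation and the full study bundle
# ---------------------------------------------------------------------------

def simulate_annotation(
    truth: SimulationTruth,
    seed: int = 0,
    plasmid_fraction: float = 0.20,
    plasmid_fraction_exp_high: float = 0.033,
    plasmid_fraction_stat_high: float = 0.28,
) -> GenomeAnnotation:
    """Assign replicons so plasmid genes lean toward the stationary class.

    The two plasmids together carry ~20% of all genes overall, but the
    exponential-high class draws plasmid genes at only ~3% while the
    stationary-high class draws them at ~28%, emulating the observed
    association of plasmid-encoded functions with stationary-phase
    physiology.
    """
    if truth.archetype_of is None:
        raise ValueError("truth carries no archetype labels")
    rng = np.random.default_rng(seed)
    frac = {
        "EXP_HIGH": plasmid_fraction_exp_high,
        "STAT_HIGH": plasmid_fraction_stat_high,
    }
    replicon_of: dict[str, str] = {}
    for g, cls in truth.archetype_of.items():
        p = frac.get(cls, plasmid_fraction)
        if rng.random() < p:
            replicon_of[g] = "pNRC100" if rng.random() < 0.4 else "pNRC200"
        else:
            replicon_of[g] = "Chromosome"
    return GenomeAnnotation(replicon_of)


@dataclass
class StudyBundle:
    """Everything one simulated growth study produces."""

    growth_curves: list[GrowthCurve]
    phases: dict[str, PhaseAnnotation]  # per strain
    expression: ExpressionMatrix  # both strains, concatenated columns
    truth: SimulationTruth
    annotation: GenomeAnnotation
    morphology: pd.DataFrame
    morphology_truth: SimulationTruth
    metabolites: pd.DataFrame
    metabolite_truth: SimulationTruth

    def strain_matrix(self, strain: str) -> ExpressionMatrix:
        return self.expression.subset_strain(strain)


#: Morphology trajectory of the default study: rods dominate during
#: exponential growth, a transient spherical pulse appears at the
#: transition, and the population returns toward rods afterwards.
DEFAULT_MORPH_TRAJECTORY = [
    (0.10, 0.35, 0.85, 0.08, 0.05),
    (0.10, 0.33, 0.85, 0.08, 0.05),
    (0.12, 0.30, 0.82, 0.08, 0.05),
    (0.15, 0.30, 0.82, 0.08, 0.05),
    (0.40, 0.35, 0.88, 0.08, 0.05),
    (0.40, 0.35, 0.90, 0.08, 0.05),
    (0.15, 0.35, 0.85, 0.08, 0.05),
]


def simulate_study(
    seed: int = 0,
    class_sizes: dict[str, int] | None = None,
    effect: float = 1.0,
    sigma_add: float = 0.1,
    sigma_mult: float = 0.1,
    n_strain_diff: int = 31,
    strain_diff_effect: float = 1.5,
    n_cells: int = 500,
    n_metab_features: int = 150,
    n_metab_concordant: int = 10,
) -> StudyBundle:
    """Simulate the full default study.

    Two strains are profiled over a shared growth design: the wild type at
    7 harvests and the mutant at 6, each as duplicate cultures with one
    dye-flip per harvest (26 sample columns at the default design).  A set
    of ``n_strain_diff`` null-background genes receives a constant log10
    shift in the mutant to plant strain-specific differences; morphology
    and metabolite tables are generated alongside with their own truths.
    """
    if class_sizes is None:
        class_sizes = dict(DEFAULT_CLASS_SIZES)
    rng = np.random.default_rng(seed)

    # growth curves: duplicate cultures per strain.  The sampling times are
    # chosen so the mu-threshold phase annotation of the noiseless curve
    # reproduces the planted labels (one early point, three exponential,
    # two transition, one stationary); the mutant skips the first harvest.
    curves: list[GrowthCurve] = []
    times7 = np.array([3.0, 10.0, 24.0, 28.0, 31.0, 48.0, 52.0])
    times6 = times7[1:]
    for strain, times, mu in (("NRC-1", times7, 0.25), ("MPK407", times6, 0.22)):
        for rep in ("A", "B"):
            curves.append(
                simulate_growth_curve(
                    mu_max=mu, od0=0.02, od_max=1.0, lag_h=16.0,
                    secondary_rise=0.15, times=times,
                    noise_cv=0.01, seed=int(rng.integers(2**31)),
                    strain=strain, replicate=rep,
                )
            )

    labels7 = default_phase_labels(7)
    phases = {
        "NRC-1": make_phase_annotation(labels7, times7),
        # time-matched with the wild type: same labels minus the first harvest
        "MPK407": make_phase_annotation(labels7[1:], times6),
    }

    # expression: same genes in both strains; strain shift planted in the
    # mutant on null-background genes
    gene_count = sum(class_sizes.values())
    n_null = int(class_sizes.get("NULL", 0))
    null_ids = [f"SYN{i:04d}" for i in range(gene_count)][-n_null:] if n_null else []
    if n_strain_diff > len(null_ids):
        raise ValueError("not enough null genes to plant strain differences")
    diff_genes = list(rng.choice(null_ids, size=n_strain_diff, replace=False))
    shifts = {
        g: (strain_diff_effect if rng.random() < 0.5 else -strain_diff_effect) for g in diff_genes
    }

    od7 = np.array([c.od600 for c in curves[:2]]).mean(axis=0)
    od6 = np.array([c.od600 for c in curves[2:]]).mean(axis=0)
    wt, truth = simulate_expression(
        class_sizes, phases["NRC-1"], effect=effect, sigma_add=sigma_add,
        sigma_mult=sigma_mult, replicates=2, dye_flip=True,
        seed=int(rng.integers(2**31)), strain="NRC-1", od600=od7,
    )
    mut, _ = simulate_expression(
        class_sizes, phases["MPK407"], effect=effect, sigma_add=sigma_add,
        sigma_mult=sigma_mult, replicates=2, dye_flip=True,
        seed=int(rng.integers(2**31)), strain="MPK407", od600=od6,
        strain_shift=shifts,
    )
    combined = ExpressionMatrix(
        wt.gene_ids,
        list(wt.samples) + list(mut.samples),
        np.concatenate([wt.log10_ratio, mut.log10_ratio], axis=1),
        np.concatenate([wt.lam, mut.lam], axis=1) if wt.lam is not None else None,
    )
    truth.strain_diff_genes = shifts

    annotation = simulate_annotation(truth, seed=int(rng.integers(2**31)))
    morph, morph_truth = simulate_morphology(
        DEFAULT_MORPH_TRAJECTORY, n_cells=n_cells, seed=int(rng.integers(2**31))
    )
    metab, metab_truth = simulate_metabolites(
        n_features=n_metab_features, n_concordant=n_metab_concordant,
        seed=int(rng.integers(2**31)),
    )
    return StudyBundle(
        growth_curves=curves,
        phases=phases,
        expression=combined,
        truth=truth,
        annotation=annotation,
        morphology=morph,
        morphology_truth=morph_truth,
        metabolites=metab,
        metabolite_truth=metab_truth,
    )
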