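# Methods

This note records the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing a
run.

## Growth curves and phase annotation

The specific growth rate μ(t) = d ln(OD)/dt is estimated by central finite
differences on ln OD (one-sided at the ends), which is exact for pure
exponential growth.  No smoothing is applied by default; an optional
odd-width moving average on ln OD is available for noisy curves.

Growth-phase boundaries are not observable quantities, so the partition is
defined operationally on μ relative to its maximum:

* EXPONENTIAL: the contiguous block around argmax μ with μ ≥ f_exp·μ_max
  (default f_exp = 0.5);
* EARLY: all points before that block;
* STATIONARY: the trailing block with μ ≤ f_stat·μ_max (default
  f_stat = 0.1);
* TRANSITION: everything between.

Both fractions are configurable and are carried in every `PhaseAnnotation`
so downstream outputs are explicit about the convention.  The definition
is monotone (raising f_exp never grows the exponential block) and places
the four phases in a fixed order, which the annotation type enforces.

Replicate agreement is the root-mean-square distance between OD values at
matched sampling times (tolerance 1e-6 h).  Interpolation is deliberately
not performed: replicate cultures of one experiment share a sampling
design, and interpolating across a lag or a secondary rise would
manufacture agreement.

## The λ statistic and persistence filter

Two-color ratio arrays are modelled with a global two-parameter error
model on the non-logged ratio scale,

    x = μ (1 + ε_mult) + ε_add,    ε ~ independent Gaussians,

so an observation around true ratio μ has variance
v(μ) = σ²_add + μ² σ²_mult.  The two scales are fitted once across all
genes by maximizing the likelihood of within-gene replicate residuals;
the gene means enter v(μ) and give the contrast that separates the
additive from the multiplicative component.  The fit needs ≥ 100 genes
with ≥ 2 replicates; on (near) noise-free data both scales hit their
lower bound (1e-6) and the result is flagged degenerate.

Per gene and condition (a condition = all samples of one strain at one
harvest, i.e. duplicate cultures and dye orientations), the significance
of change is the likelihood ratio for H₀: μ = 1 with the variance
evaluated at the estimated mean and treated as known:

    λ = m (x̄ − 1)² / (σ²_add + x̄² σ²_mult).

This plug-in convention — rather than profiling the variance over μ —
keeps two properties that the full profile likelihood would break: λ is
exactly 0 when the replicate ratios average to 1 (the −log v(μ) term would
otherwise pull the optimum off the null even for data identical to it),
and λ is exactly χ²(1)-distributed under the null when the error model
holds with known scales.  Monte-Carlo calibration (10,000 null genes,
fitted scales) puts the rejection rate at the χ²(1) 95th percentile within
0.05 ± 0.01.

The persistence filter retains a gene when λ > λ₀ strictly (default 15)
over at least k consecutive growth-ordered data points (default 4),
duplicate cultures included: the duplicate columns are interleaved in OD
order, so a run of 4 typically spans 2 harvests × 2 cultures.  Missing λ
values break runs (conservative).  Runs are scanned within each strain's
column block separately and the per-strain significant sets are united.
Threshold sweep tables report counts over a (λ₀, k) grid; counts are
non-increasing in both arguments by construction and this invariant is
asserted at run time.

Dye-flip handling: stored log10 ratios are always orientation-corrected,
with the flip recorded in the sample metadata.  Swapping the two channels
of every hybridization therefore inverts the raw ratios and toggles the
flags but leaves the corrected matrix — and every λ — unchanged.

## Temporal archetypes

Filtered genes are row-normalized to mean 0, population sd 1 (missing
cells ignored and preserved; constant rows are an error naming the gene)
and clustered with K-means (k-means++ seeding, 25 restarts, best
within-cluster sum of squares, deterministic given the seed; backed by
scikit-learn).  K defaults to 10: the biological classes of interest are
five, but letting K exceed the class count absorbs noise substructure, and
cluster labels — not cluster identities — are what downstream stages use.

Each centroid is classified from its phase-segment means E, X, T, S with
margin δ (default 0.5 normalized units):

| label | rule |
|---|---|
| TRANSIENT_UP_EXP | X − E ≥ δ and X − S ≥ δ |
| TRANSIENT_DOWN_EXP | E − X ≥ δ and S − X ≥ δ |
| TRANSIENT_UP_TRANSITION | T − X ≥ δ and T − S ≥ δ |
| EXP_HIGH | X − S ≥ δ and X ≥ E − δ |
| STAT_HIGH | S − X ≥ δ |
| OTHER | none of the above |

Rules are checked in table order: pulses take precedence over steps so a
transient is never mislabelled as a monotone class.  All rules use
differences only, so labels are invariant to adding a constant to a
centroid.  A rule whose required phase segment is absent from the design
is skipped and logged.

Enrichment of a gene set in a replicon (or any category) is the exact
hypergeometric tail (scipy), reported with its direction: upper tail when
k/n > K/N, lower tail otherwise.

## Strain comparison

Fold change over the growth curve is the mean non-logged ratio of the last
four growth-ordered samples (replicates included) over the mean of the
first four.

The between-strain test is a per-gene Welch t on logged values with
permutation p-values: p = (1 + #{|t*| ≥ |t|}) / (B + 1) for B sampled
label permutations, or the exact fraction when all C(n_a+n_b, n_a)
arrangements fit the budget (then complementary splits tie in |t|, so the
attainable floor on a 4-vs-4 design is 2/70).  Genes constant in both
groups get p = 1 with a warning.  The significant set is chosen by a
false-significant-proportion step: among |t| thresholds attained by genes
with p ≤ α (default 0.01), the loosest threshold is kept whose median
permutation exceedance count, divided by the observed count, stays below
the bound (default 0.01).  This is a SAM-style estimate; the historical
microarray-suite implementation of the same idea is not bit-reproducible,
so agreement is by calibration properties (type-I error, p-value validity,
enumeration equivalence), not by matching historical gene lists.

The endpoint change test compares each gene's first four against last four
samples (Welch t on logged values) with Benjamini–Hochberg control
(default rate 0.05) and an overall p ≤ α gate; it emits fold change, t, p,
q and a 0/1 flag per gene.

## Morphology mixtures

Per-cell shape metrics come from scikit-image region properties on a
single-component binary mask of ≥ 20 pixels: area as pixel count,
perimeter by the corner-corrected crack-length estimator (so a rasterized
disc lands near C = 1 instead of overshooting), circularity
C = min(1, 4πA/P²), and axis lengths from second central moments.

Circularities at one timepoint are fitted with a two-component Gaussian
mixture by EM.  Initialization splits the sample at its 40th percentile
(spherical cells are typically the minority); each σ is floored at 1e-3
against component collapse; convergence is a log-likelihood gain below
1e-8; non-convergence after 500 iterations returns the last iterate
flagged, with a warning, rather than raising.  Components are ordered
μ₁ ≤ μ₂ on output (component 1 = rods), which resolves label switching
deterministically.  The observed-data log-likelihood is recorded after
every iteration and is non-decreasing — a property the test suite asserts
on every fit it makes.  Fits with |μ₂ − μ₁| < max(σ₁, σ₂) are flagged as
overlapping (weakly identified).  The Gaussian family is used on (0, 1]
with a range check rather than a truncated likelihood, mirroring common
mixture tooling; at the circularity scales involved the truncation mass is
negligible.  A minimum of 50 cells per timepoint is required (overridable
with a warning).

Population trajectories fit each timepoint warm-started from the previous
one, which stabilizes component labelling along the growth curve.  The
gas-vesicle index is the median of per-cell mean intensities — robust to
the bright outliers free-floating vesicle clusters produce.

## Metabolite filters and concordance

Features are retained when the early-vs-stationary contrast passes both a
pooled-variance Student t test on log10 abundances (p < 0.001) and a
phase-mean fold change ≥ 3 in either direction (inclusive).  The Student
form is used rather than Welch deliberately: with triplicate harvests the
Welch–Satterthwaite degrees of freedom collapse to ~2–4 and the test loses
most of its power, while equal design variance across harvests is part of
the measurement model; with equal group sizes the statistic itself is
identical.  Exact zero abundances are replaced by half the smallest
positive replicate before logging; a zero phase mean opposite a positive
one yields an infinite fold, which passes the fold criterion (logged).

A gene group's three-phase profile is the mean non-logged ratio over the
samples of each of EARLY/EXPONENTIAL/STATIONARY, standardized to mean 0,
sd 1 across the three phases.  Concordance between a metabolite and a gene
group is the Pearson correlation of their standardized three-phase
profiles — with three points this is the natural bounded, affine-invariant
similarity; a rank-based variant would be degenerate at this length.

## The synthetic-data generator

Growth curves follow a Baranyi-Roberts trajectory (logistic growth toward
od_max preceded by an adjustment lag), plus an optional delayed sigmoidal
secondary OD rise emulating the light scattering of gas vesicles released
late in an experiment, and optional multiplicative lognormal measurement
noise.  The default study design is two strains — the wild type sampled at
7 harvests (t = 3, 10, 24, 28, 31, 48, 52 h; lag 16 h, μ_max 0.25/h,
od0 = 0.02, od_max 1.0) and a mutant at the same times minus the first —
as duplicate cultures with one dye-flip per harvest: 26 sample columns.
The harvest times were fixed once so that the μ-threshold annotation of
the noiseless curve reproduces the planted labels (EARLY,
3 × EXPONENTIAL, 2 × TRANSITION, STATIONARY); an even phase split is not
attainable because a finite difference spanning the lag-to-growth window
always looks exponential.

Expression: each gene's mean log10-ratio trajectory is a piecewise-
constant template over the phase labels, scaled by the effect size
(default 1.0 log10 units); the five archetype templates are steps
(±1, ±1, 0, ∓1) and single-segment pulses.  Default class sizes are 451
exponential-high, 772 stationary-high, 10/4/18 transients and 1145 nulls
(2400 genes).  Observations carry the same additive+multiplicative noise
family the significance module fits (defaults σ_add = σ_mult = 0.1), and λ
values are computed from the simulated replicate structure through the
significance module itself — the generator plants means, never λ values.
31 null-background genes receive a ±1.5 log10 shift in the mutant to plant
strain-specific differences.  Replicons are assigned so plasmids hold ~20%
of the genome but only ~3% of the exponential-high and ~28% of the
stationary-high class, planting the plasmid/stationary association at
recoverable strength.

Morphology: circularities are drawn from planted per-timepoint
two-component mixtures truncated to (0, 1] by resampling (not clipping, so
the mixture family stays well-specified); the default trajectory holds w₂
near 0.1 through exponential growth, pulses to 0.4 at the transition and
relaxes back.  Axis lengths are filled consistently (aspect ratio 1/C), so
low circularity implies elongation.

Metabolites: concordant features follow a three-phase gene-group profile
rescaled so the early-to-stationary ratio is exactly the requested fold
(default 4, direction per the profile; default profile dips in exponential
phase and rises into stationary); background features are flat.
Replicates (default 3) carry multiplicative Gaussian noise (default CV
0.1).

What the generator does not emulate: spatial array artifacts, per-spot
image statistics, dye-specific intensity bias beyond the orientation flag,
chromatogram structure, cell segmentation errors, and any correlation
between a gene's archetype and its metabolite pathway.  Recovery results
on synthetic data therefore speak to the statistical machinery — filter
operating characteristics, calibration, parameter recovery — not to
robustness against those instrument-level artifacts.

## Numerical conventions and problem sizes

* One TSV/CSV dialect everywhere: tab separation, UTF-8, mandatory header,
  `NA` missing token, `.` decimal, floats at 17 significant digits; reads
  use round-trip float parsing, so write/read is bit-exact.
* Row normalization uses the population (n) standard deviation.
* Summary percentages use round-half-up integer rounding.
* All randomness flows through `numpy.random.default_rng` seeds; every
  simulator is a pure function of parameters and seed, and a fixed
  config+seed reproduces a pipeline run byte for byte.
* The test suite and the acceptance script run their calibration
  experiments at 10,000 null genes (λ), 1,000 null genes (permutation
  test), 5,000 genes (error-model recovery), 100 seeds × 500 cells
  (mixture recovery) and 1,000 random matrices (filter oracle checks) —
  sizes at which the Monte-Carlo error is comfortably inside the asserted
  tolerances while a full run stays in the tens of seconds.

## Known limitations

* The λ statistic shares only its error-model family with the historical
  maximum-likelihood array statistic it stands in for; absolute λ values
  are not comparable across implementations, which is why acceptance rests
  on calibration properties and count orderings rather than value
  matching.
* The false-significant-proportion step estimates the null exceedance
  count by the median across permutations; alternatives (mean, quantile)
  shift the threshold slightly on small designs.
* Phase boundaries from finite-difference μ on sparse (6–7 point) designs
  are sensitive to the sampling times; the planted-design agreement is
  ≥ 6 of 7 points, not exact.
* The Gaussian mixture ignores truncation at C = 1; for populations with
  μ₂ within ~2σ₂ of 1 the fitted μ₂ biases slightly low.
* With only three phases, concordance scores take few distinct values and
  should be read as pattern matches, not calibrated statistics.
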