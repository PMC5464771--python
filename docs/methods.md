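# Methods

This note records the models behind each stage, the defaults and why they
are what they are, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Migration-track analytics

A track is a time-ordered sequence of 2D positions (µm) at a nominally
uniform frame interval (default acquisition: one frame every 5 s, 5-min
tracks, so 61 points). Three statistics are computed:

* **Instantaneous speed** — Euclidean step length divided by the step
  duration, reported in µm/min. Irregular frame intervals are accepted
  with a warning; per-step durations are always used, so speeds remain
  correct.
* **Maximum excursion** — the largest Euclidean distance between *any*
  two points of the track. This deliberately differs from both net
  displacement (which it bounds from above) and path length: a cell that
  wanders out and back scores its farthest separation, not its mileage.
  Computed via all-pairs distances; tracks are short (~60 points) so the
  O(n²) cost is irrelevant, and an explicit double-loop oracle in the
  tests guards the implementation.
* **Arrest call** — arrested iff the maximum excursion is *strictly*
  below 10 µm for a 5-min (300 s) window; an excursion of exactly 10 µm
  is migrating. Equivalent to a rate threshold of 2 µm/min, which is how
  the threshold is scaled for tracks of non-standard duration
  (threshold × duration / window). Zero-duration tracks cannot be
  classified and raise.

Cohort velocity statistics (mean, SEM of per-track mean speeds) are
computed over migrating tracks only — matching the convention of
reporting "velocities of migrating cells" — with all-track statistics
exposed alongside for deceleration analyses. Tracks with fewer than 3
points are excluded from velocity statistics (too few steps for a stable
mean) but still counted in the arrest fraction; exclusions are logged.
Whether border-touching cells or gapped tracks should be excluded is an
upstream-tracking policy, not asserted here; the reader accepts whatever
rows the spot table contains.

## Hertz indentation fitting

Geometry: a stiffness-calibrated cantilever (k = 3 nN/µm by default) with
a spherical glass tip (R = 5.7 µm) indents a cell from above while the
cell rests on a rigid support. Lowering the base by D deflects the
cantilever by D − d, giving F = k(D − d); the tip displacement d *is* the
indentation depth δ in this geometry. Curves are assumed pre-zeroed at
contact; a manual `contact_offset` shifts δ, and automatic contact-point
detection is out of scope. No bottom-effect (finite-thickness) correction
is applied, and viscoelasticity is ignored — the measurement protocol
indents slowly (< 0.5 µm/s) precisely so the elastic model applies.

The spherical Hertz model with an incompressible sample (ν_cell = 0.5)
and rigid probe (glass is ~10⁶× stiffer, so the two-material reduced
modulus 1/E* = (1−ν_cell²)/E_cell + (1−ν_probe²)/E_probe collapses to
E* = E_cell/(1−ν_cell²)) gives F = (16/9)√R·E_cell·δ^{3/2}. The model is
linear in E_cell, so the least-squares fit is the closed-form slope
Σ xF / Σ x² with x = (16/9)√R δ^{3/2} — identical optimum to any
iterative fit, with no initialisation or convergence concerns. The slope
is constrained to E ≥ 0: a negative slope (pure-noise curve) is clamped
to zero with a warning and flagged in the result. Points with δ ≤ 0
after offsetting are dropped and logged. With forces in nN and lengths in
µm the slope is in nN/µm² = kPa; results are reported in Pa. The fit
accepts a single positive-δ point (closed-form inversion); the default
fit window is all positive-δ points, with an optional δ_max, since the
depth range used in practice ("a few microns") is not sharply bounded.

## Gel rheology

The storage modulus G′ of a gel disc is measured at 5% strain while the
rheometer gap is decreased; G′ rises as the sample is progressively
loaded and saturates at full contact. The characteristic modulus is the
**maximum of G′ over the sweep** — deliberately the raw maximum with no
smoothing or plateau-detection heuristic, reproducing the standard
estimator including its (slight, noise-upward) bias. Young's modulus
follows as E = 2(1+ν)G′ with ν = 0.45 for polyacrylamide, a conversion
factor of exactly 2.9; at ν = 0.5 it reduces to the incompressible
E = 3G′. Per-sample conversion before averaging is the default; by
linearity the cohort mean is identical either way, and both SDs (differing
by the factor 2.9) are reported. The stiffest (18% acrylamide, ~100 kPa)
formulation's modulus is a cited literature constant, carried in the
fixture table with basis `"reported"` rather than computed from a sweep.

## Ligand surface density

The chain: acrylamide molarity of the mix is 10·(% w/v)/71.08 mol/L
(71.08 g/mol is the acrylamide monomer molar mass, a documented constant
of this module); streptavidin-acrylamide molarity is that times the molar
ratio (1/100 000); hydration swells the cast volume by a factor 1.4, so
the hydrated-gel concentration is the mix molarity / 1.4, converted via
Avogadro's number to molecules/µm³; multiplying by the 10 nm accessible
surface depth (about one streptavidin diameter — deeper molecules are
hidden by ~15 nm pores) gives the areal density. For the standard
5%-acrylamide recipe this is 30.3 molecules/µm², inside the published
20–40 band; disc diameter and gel thickness cancel exactly, which is
asserted as a property test over random geometries. Because of that
cancellation the published band cannot be reconstructed by propagating
the 25–50 µm thickness range through the chain — rounded intermediate
volumes give the same density at both thicknesses — so the band is
treated as a printed envelope around the point estimate, and the module
reports the point estimate.

Minority-species densities for a 1:N coating mixture follow the
divide-by-N convention (30/µm² at 1:10 → 3/µm², inside the published 2–4
band). This over-counts relative to a strict partition of sites
(site/(1+N)); both values are reported, divide-by-N as primary, since it
is the arithmetic the published densities follow. Bis-acrylamide is
excluded from the monomer molarity (the molar ratio is defined against
acrylamide alone). The fixed 1/100 000 ratio makes the density scale with
acrylamide %, so the three gel recipes give different point estimates;
the fixture table records them per recipe without attempting to
reconcile this with the claim that one band covers all gels.

## Synthetic generators

All generators are bit-reproducible under a fixed integer seed
(`numpy.random.default_rng`).

**Tracks.** Each cell is independently arrested with probability
`frac_arrested`. Arrested cells take isotropic Gaussian steps (SD 0.1 µm
per frame per axis — a 5-min arrested track then stays far below the
10 µm threshold). Migrating cells follow a persistent random walk:
per-step turning angles are Gaussian with SD (1 − persistence)·π rad
(default persistence 0.7, a value typical of crawling lymphocytes and
unconstrained by any printed number). Each migrating cell draws its own
mean speed from a truncated-at-zero Gaussian whose SD is the
**between-cell** SD; step speeds then fluctuate around the cell mean with
a fixed CV of 0.25. The between-cell placement of the SD is what lets the
fixture SDs (3–4 µm/min) reproduce the printed cohort SEMs (0.3–0.4
µm/min at n ≈ 100); putting all the variance at the step level would
shrink cohort SEMs ~8-fold and make the printed values unreachable.
What the generator does *not* emulate: field-border effects, tracking
gaps and mislinks, speed autocorrelation beyond first-order persistence,
substrate heterogeneity, and cell–cell interactions — so passing recovery
tests demonstrate estimator correctness, not tracker robustness. A small
fraction (~2% at the stiff-gel fixture) of nominally migrating cells
drawn with low speeds legitimately falls below the arrest threshold; the
classifier reports observed arrest, so simulated arrest fractions sit
within ~2 percentage points of the assigned probability.

**Indentation.** δ runs linearly over (0, δ_max = 2 µm] (50 points);
F = (16/9)√R·E·δ^{3/2}·(1+ε) with multiplicative Gaussian noise
ε ~ N(0, cv²) (default cv 3%, clipped so F ≥ 0); raw pairs are emitted as
D = δ + F/k, d = δ, so the raw-conversion step inverts the construction
exactly at zero noise. Multiplicative force noise keeps the closed-form
slope estimator unbiased, which the recovery tests exploit. Drift,
adhesion (snap-in/out), and contact-point uncertainty are not modelled.

**Gap sweeps.** Gaps run from 1.10 to 0.90 mm (12 points, decreasing as
acquired); the noiseless profile is plateau·exp(−shape·(gap − gap_min)/span)
(shape 3), exactly equal to the plateau at the smallest gap so the
max-estimator is exact at zero noise; additive Gaussian noise (default SD
20 Pa, ~1% of a 2.2 kPa plateau) is clipped at zero. Instrument
compliance and sample slip are not modelled.

**Fixtures.** `fixtures.json` carries the per-condition anchors with a
`source` label per entry: `figure` (printed mean ± SEM), `reported`
(cited constant), `invented-ordering-only` (chosen here; only the
ordering across conditions is anchored — used for the TCR-triggered
arrest fractions, which are figure-encoded and never printed as numbers).

## Problem sizes and tolerances

Recovery tests use the cohort and replicate sizes of the underlying
assays: 100-cell migration cohorts (tolerance 3 SEM = 1.2 µm/min on the
cohort mean), 200 indentation curves at 3% noise (mean fitted modulus
within 2% of truth), single sweeps at ~1% noise (plateau within 3 noise
SD). Deterministic closed forms (unit conversions, the 2.9 factor, the
density chain) are checked at printed precision or tighter. Excursion
uses exact arithmetic against an O(n²) oracle on 1000 random tracks of up
to 50 points.

## Known limitations

* The arrest rule is a hard threshold on one statistic; cells hovering
  near 10 µm/5 min flip classification under small noise, and the
  percent-arrested statistic inherits that sensitivity.
* The plateau-as-maximum estimator is biased upward by measurement noise
  (by roughly the expected maximum of the per-gap noise); this is kept by
  design for comparability.
* The Hertz stage assumes a pre-zeroed contact point, a rigid flat
  support, infinite sample thickness and pure elasticity; violations bias
  E_cell in ways the toolkit does not correct.
* The density model is theoretical: it assumes complete streptavidin
  incorporation and full accessibility within the top 10 nm, and is not a
  substitute for fluorescence-based coating quantification.
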