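# Methods

## The counting model

`wellcount` quantifies particle or cell number density by limiting
dilution ("digital" counting) on a microwell array. A liquid sample is
partitioned into n identical wells of volume V (µL). Under random
loading, the number of particles in a well is Poisson with mean
λ = c·V, where c is the number density (particles/µL). The probability
that a well is *occupied* (≥ 1 particle) is

    p = 1 − e^(−λ)

Observing k occupied wells out of n inverts this relation:

    p̂ = k/n,   λ̂ = −ln(1 − p̂),   ĉ = λ̂ / V

The estimator never counts individual particles — only the binary
occupied/empty state of each well — which is what makes it insensitive
to particle shape and, for recognition purposes, to aggregates.

### Confidence intervals

The uncertainty in ĉ is binomial uncertainty in p̂ propagated through a
strictly monotone transform, so any binomial interval [p_lo, p_hi] maps
endpoint-wise to [−ln(1−p_lo)/V, −ln(1−p_hi)/V] with its coverage intact.
The default interval is the Wilson score interval (well-behaved at k near
0 and n, unlike the Wald interval); Clopper–Pearson is available via
`ci_method="clopper-pearson"` for guaranteed-coverage use. The default
confidence level is 0.95. The transform is not linear, so the mapped
interval is asymmetric about ĉ; the summary statistic
`ci_percent_of_mean` is defined as 100·(hi − lo)/(2·ĉ), the half-width
as a percentage of the estimate.

Edge cases:

* k = 0 — ĉ = 0 with a finite upper bound; the lower bound is 0.
* k = n — λ is unidentifiable (p̂ = 1 maps to infinity). `estimate_density`
  raises `SaturationError` carrying the one-sided lower density bound at
  the requested confidence level rather than returning a number.
* Ties at the threshold during classification count as unoccupied, the
  conservative direction for a density estimate.

## Reference geometry

The default `ArrayGeometry` describes a PDMS device of 36 panels, each a
30 × 30 square lattice of circular wells with 20 µm diameter and 25 µm
depth. The cylinder volume of such a well is π·10²·25 µm³ =
7.854 × 10⁻⁶ µL, and this geometry-derived value is the default V.

Two published values for this device do not follow from that geometry
and are kept verbatim as named constants rather than reconciled:

* `PRINTED_WELL_VOLUME_UL` = 1.257 × 10⁻⁵ µL — the quoted per-well
  volume; it equals π·10²·40 µm³, not the cylinder volume of the stated
  20 µm × 25 µm well.
* `PRINTED_WELLS_PER_DEVICE` = 14,400 — the quoted device well count;
  the stated 36 × (30 × 30) layout multiplies to 32,400. The product
  14,400 × 1.257 × 10⁻⁵ µL reproduces the quoted 0.18 µL total.

`wells_per_device` always equals rows·cols·panels; a config file may
override `well_volume_ul` explicitly to reproduce the published
arithmetic.

Two parameters of the physical device are not published and are free
parameters here, fixed at values typical of PDMS microwell arrays:

* centre-to-centre pitch: 40 µm (twice the well diameter, leaving a
  20 µm wall);
* pixel scale: 1 µm/px by default (20 µm well ≈ 20 px across, the scale
  at which a 4×–10× objective images such arrays). Monte-Carlo-heavy
  tests and the acceptance script run at 2 µm/px, which quarters the
  pixel count per panel without changing any measured occupancy in our
  test conditions.

## Synthetic data generator

The generator produces panel images with exact ground truth, emulating
what the recognition chain actually consumes rather than the microscope
optics.

**Loading model.** Per-well particle counts at aggregation a = 0 are
i.i.d. Poisson(λ). For a > 0, particles arrive in clumps: clumps per
well are Poisson(λ(1−a)) and each clump holds Geometric(1−a) particles
(support ≥ 1), so per-well counts are compound-Poisson with unchanged
mean λ while the occupied fraction drops to 1 − e^(−λ(1−a)). This is the
simplest mechanism that reproduces the under-counting observed with
aggregating particles at high density — the data no longer satisfy the
Poisson occupancy relation, so λ̂ computed from occupancy alone
underestimates the true density. No correction is attempted; the bias is
reproduced, as the method's documented limitation, not fixed.

**Rendering.** Bright-field: bright background (0.85), a darker rim
annulus (0.35, 2 px wide) at each well, interior 0.78, particles drawn
as dark disks (0.15) of radius 0.5·R (a 10 µm bead in a 20 µm well) at
uniform-random sub-well positions, overlap with the rim allowed.
Fluorescence inverts the polarity: dark background (0.05), faintly
visible well interiors (0.22), bright particle disks (0.85). The
contrast constants stand in for per-device illumination/shutter
adjustment on a real microscope and are overridable via
`RenderSettings`; the defaults guarantee that occupied and unoccupied
interior means are separated by far more than 5× the default noise
σ = 0.02, i.e. a cleanly bimodal well-intensity histogram. Noise is
additive Gaussian plus a multiplicative linear illumination tilt along
the image diagonal (default full-frame amplitude 10%), then clipping to
[0, 1]. Wells listed in `missing_wells` (fabrication defects) are not
drawn at all and receive no particles.

Everything is deterministic given the seed; the same seed yields
bit-identical ground truth and pixels.

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about real micrographs: point-spread blur and
defocus, vignetting beyond a linear tilt, debris between wells,
partially filled wells with intermediate intensity, cell autofluorescence
variation, sensor fixed-pattern noise, and panel-to-panel illumination
changes (a real device may need per-panel thresholds; both pooling modes
are provided). Real images also require cropping to the panel region,
which is assumed already done.

## Recognition chain

1. **Denoising** — mean-kernel filter (default 3 × 3, reflect padding),
   the smallest kernel that suppresses pixel noise without eroding a
   ≈ 20 px well; kernel 1 is the identity.
2. **Circle detection** — Canny edges (σ = 1) followed by a circular
   Hough transform restricted to radii within ±1 µm of the nominal well
   radius (±½ px quantisation slack). Restricting the radius band is
   what rejects structured clutter of the wrong size. Accumulator peaks
   are normalised (1.0 = full circle of edge pixels); peaks below the
   accumulator threshold (default 0.5) are discarded — in the
   generator's contrast regime true rims score ≥ 0.53 and wrong-radius
   clutter ≤ 0.4 — and surviving peaks closer than pitch/2 are merged to
   the stronger peak, so at most one detection survives per well and
   anything *inside* a well (particles, aggregates) can never add a
   detection. The threshold is exposed because suitable Hough parameters
   are device/illumination dependent.
3. **Grid fit** — detected x and y coordinates are clustered with a gap
   threshold of pitch/2; cluster medians get lattice indices by rounding
   against the nominal pitch; least squares of position on index gives
   origin and pitch per axis. A refinement pass assigns every circle to
   its nearest lattice site and re-solves with shear terms, absorbing
   small camera rotation (≲ 1°; larger rotations would break the initial
   axis-aligned clustering and are out of scope). Every well receives a
   fitted centre whether or not it was detected, so the number of
   analysed wells is always rows × cols — occupancy and filling defects
   change the detection count, never the analysis count. The fit fails
   loudly (`GridFitError`, naming the deficiency) when fewer than two
   rows or columns are detected, when detections land on conflicting
   lattice indices, or when RMS residuals exceed pitch/4. If an edge row
   or column of the lattice has no detections at all, index 0 is
   anchored at the first detected line; with ≤ 7% random missing wells
   this is never ambiguous (30 wells per line), but a fully absent
   border line would shift the grid by one pitch.

## Classification

Per-well mean intensity is averaged over a disk of 0.8 × fitted radius
(excluding rim pixels, which would otherwise darken unoccupied means).
The threshold is placed at the minimum of the Gaussian-KDE-smoothed
intensity density between the *unoccupied* mode — the extreme
significant mode on the unoccupied side of the modality's polarity:
brightest in bright-field, dimmest in fluorescence — and the adjacent
significant mode (prominence ≥ 5% of the density maximum). In the
canonical two-mode histogram this is exactly the valley between the two
largest modes; anchoring on the polarity-extreme mode additionally
survives high occupancy, where wells holding 1, 2, 3… particles split
the occupied side into sub-modes that can each outgrow the unoccupied
peak. A unimodal density carries no evidence of occupancy and yields a
sentinel threshold classifying every well as unoccupied — note this
means a *fully saturated* device (every well occupied, also unimodal)
auto-thresholds to k = 0; distinguishing the two from well intensities
alone is impossible without a contrast calibration, which is why a
manual threshold override exists. Intensities from all panels of a
device are pooled into one histogram by default (one illumination
setting per device); per-panel thresholding is available.

The result histogram uses Freedman–Diaconis binning floored at 16 bins.

## Design simulator

* `ci_vs_well_count` — CI% of mean against n at fixed density,
  analytically (expected occupancy k = n·p pushed through the
  estimator) or by Monte Carlo (k ~ Binomial(n, p), mean CI% over reps;
  draws at k = 0 or n carry no finite interval and are dropped with a
  warning). The analytic curve shrinks as 1/√n: 16× the wells gives 4×
  the precision.
* `density_vs_volume` — the closed form c = −ln(1−f)/V per occupied
  fraction f, a slope −1 line in log–log axes: the well volume sets the
  measurable density range (1 nL wells → ~10⁶/µL at λ = 1).
* `end_to_end_recovery` — full pipeline on a synthetic device at known
  density, returning estimate and truth side by side; this is the
  harness behind the coverage and aggregation-bias checks.

## Numerical and testing choices

Problem sizes in the test suite and acceptance script were chosen to
exercise the full pipeline at single-CPU scale: statistical recovery
runs use one 30 × 30 panel per run at 2 µm/px (100 seeded runs per
occupancy level in the tests, 40 in the acceptance script; coverage and
bias bounds hold at either), aggregation bias uses 20 runs, Monte-Carlo
design curves 500 replicates. Detection-accuracy checks run at the full
1 µm/px default. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical seeds give bit-identical
outputs, and the CLI records every seed in its run manifest.

Known limitations: no optical PSF or 3-D rendering; no multi-panel
stitching (one image = one panel); no correction for aggregation bias;
no rotation handling beyond ~1°; saturation (k = n) is reported as a
bound, not an estimate; the unimodal-histogram sentinel cannot tell an
empty device from a saturated one.
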