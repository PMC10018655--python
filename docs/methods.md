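# Methods

`ctiq` evaluates image quality in paired chest-CT reconstruction
comparisons: the same patients (here, synthetic phantoms) imaged at two
dose levels and reconstructed several ways, compared through noise power
spectra, contrast-to-noise ratio (CNR), line-profile resolution probes,
visual-grading-characteristics (VGC) analysis of ordinal observer ratings,
and DLP-based effective-dose accounting.  This note records the models, the
parameters that matter, the numerical conventions, and what the synthetic
data can and cannot show.

## Power-spectrum estimation

The estimator follows standard CT noise-power-spectrum (NPS) practice
applied to images that retain anatomy — we therefore speak of a power
spectrum (PS) rather than an NPS.  Per axial slice, the central
128 × 128 px window is tiled with four non-overlapping 64 × 64 px ROIs.
Each ROI is reflected about its right and bottom edges into an
even-symmetric 128 × 128 block, which removes the periodic-boundary jumps
that would otherwise leak broadband artefact power into the spectrum of a
strongly correlated image.  After subtracting the block mean,

    PS(fx, fy) = (Δ² / N) · |DFT(block − mean)|²   [HU² mm²],

with Δ the pixel spacing in mm and N the number of block pixels.  The
examination PS is the average over all ROIs of all slices; the 1D curve is
the unweighted mean over annular bins one frequency step
(1/(128 Δ) mm⁻¹) wide, excluding the DC sample, with the bin abscissa at
the mean |f| of its samples.  Cohort curves report the per-bin relative
standard error, 100·(SD/√n)/mean, across patients.

Numerical conventions worth fixing explicitly:

* **Mean subtraction only.**  Subtracting the block mean zeroes the DC bin
  and removes sensitivity to absolute HU offsets, while anatomy-driven
  low-frequency power is deliberately retained.  No detrending or
  background fitting is applied.
* **Parseval closure.**  With the normalisation above,
  `sum(PS)·df² = block pixel variance` (n-divisor) holds exactly per block
  and therefore per examination; the test suite asserts it to float
  tolerance.
* **Window placement** is by image geometry (centred), matching a phantom
  centred in the field of view.
* **Mirrored-estimator bias.**  Reflection suppresses edge leakage but is
  not free: for spatially correlated noise the reflected (DCT-type)
  periodogram redistributes a few percent of power — roughly +30% in the
  one or two lowest frequency bins and −5% near the spectrum maximum for
  the kernels used here, independent of how many blocks are averaged.
  Comparisons *between* reconstructions at matched settings are unaffected
  (the distortion is common to both arms), but the lowest bins of any
  single curve should not be over-read.  Generator validation (below)
  therefore uses plain full-slice periodograms, which are unbiased for the
  synthetic noise.

## Synthetic phantom and noise

The phantom is a deterministic HU map: an elliptical soft-tissue body
(30 HU) on air, two lung fields (−850 HU), an ascending-aorta disk
(45 HU), an anterior mediastinal fat disk (−100 HU) and 1–4 mm vessels
(50 HU) inside the lungs.  Rasterisation uses the centre-in-shape rule;
all slices share the anatomy.  Defaults: 512 px at 0.75 mm spacing.

Reconstruction arms are emulated by three independent controls:

1. **Noise colour and magnitude.**  White Gaussian noise is shaped in the
   2D frequency domain by multiplying its FFT with the square root of a
   target radial power spectrum, then rescaled so the whole-stack SD is
   exactly `sigma_ref · dose_factor^(−1/2)` (quantum-noise dose scaling).
   Named shapes: `sharp_kernel`, a band-pass `(f/f₀)²·exp(−(f/f₀)²)` with
   f₀ = 0.25 mm⁻¹ (Lung-kernel-like texture), and `smooth_kernel`, a
   low-pass `exp(−(f/fc)²)` with fc = 0.18 mm⁻¹ (deep-learning- or
   soft-kernel-like).  Frequency-domain multiplication gives exact
   stationary control of the spectrum; the validation tests recover the
   requested filter from full-slice periodograms to well under 5% RMS over
   0.05–0.8 Nyquist (80 slices).
2. **Kernel spatial resolution.**  A Gaussian blur of the noiseless
   anatomy (σ = 0.4 mm for the sharp arm, 0.8 mm for the smooth arms)
   stands in for the reconstruction kernel's MTF.  This is what makes
   line profiles over small vessels differ between arms.
3. **Edge enhancement.**  Vendor post-processing edge filters are
   emulated by an unsharp mask, `out = in + gain·(in − blur(in, radius))`
   (gain 1.0, radius 1.5 mm by default), applied to the *noisy* image —
   so it sharpens profiles, raises high-frequency power and slightly
   lowers CNR through noise amplification, the three measurable
   consequences the analysis probes.

## ROI metrics and CNR

CNR between the aorta ROI (ROI1) and the mediastinal-fat ROI (ROI2), both
15 mm circles:

    CNR = (HU₁ − HU₂) / √(SD₁² + SD₂²).

Pixels belong to a circular ROI iff their centre lies inside it; SDs use
the n−1 divisor (with ≈314 pixels per ROI the divisor choice is
numerically negligible, but it is fixed for bit-stability).  Two
reconstructions are compared by the per-patient difference
CNR₁ − CNR₂ with its mean, standard error of the mean and a paired
two-sided t-test (df = n−1, significance read at p < 0.05).  The
difference is the plain arithmetic difference; no normalisation is
applied.  Line profiles sample the image by bilinear interpolation at a
uniform step (default half the pixel spacing; a nearest-neighbour mode
reads exact pixels), so identical mm endpoints probe identical anatomy
across reconstructions.

## Observer model and VGC analysis

Ratings are simulated from a cumulative-threshold latent model:
`latent = condition mean (0 or delta) + case effect + reader effect +
noise`, with Gaussian effects shared between the two conditions of a pair
and ascending cut-points per scale, by default centred midway between the
two condition means (five-step: delta/2 ± {0.35, 1.05}; three-step:
delta/2 ± 0.5).  Defaults mirror a 25-case × 5-reader × 10-question
study (Q1–Q6 five-step criterion scales, Q7–Q10 three-step acceptability
scales), with σ_case = 0.5, σ_reader = 0.3, σ_noise = 1.  With no
case/reader effects the model has the closed-form AUC
Φ(delta/(σ_noise·√2)), which the rank analysis recovers to Monte-Carlo
tolerance — the basis of the parameter-recovery tests.  Recovery is only
as good as the discretisation allows: rating on 5 categories leaves the
tie-corrected rank AUC ≈ 0.012 below the latent value at delta = 1 even
with optimally placed cut-points (the default spacing sits at that
minimum), and a 3-category scale leaves ≈ 0.03 — a floor intrinsic to
coarse ordinal scales, not a property of the estimator.  Raw ratings are
stored in the questionnaire's own coding (five-step: 1 = best;
three-step: 3 = best) and re-oriented to higher-is-better before
analysis.

The VGC curve plots, for each threshold t swept down the ordinal scale,
the fraction of test ratings ≥ t against the fraction of reference
ratings ≥ t, pooled over readers and cases.  The trapezoidal area under
this curve is identical to the tie-corrected pairwise statistic
`[#(test > ref) + ½·#(test = ref)] / (n_t·n_r)` — the implementation
computes the area, the test suite checks the identity against exhaustive
pair counting.  The statistic is rank-invariant: any strictly monotone
relabelling of the categories leaves it unchanged.  A binormal
alternative fits, by maximum likelihood, a latent-normal model with
shared cut-points (reference fixed at N(0,1), test at N(μ,σ)) and reports
Φ(μ/√(1+σ²)); it needs at least two categories in use and is the smooth
counterpart of the empirical estimate.

Uncertainty comes from percentile bootstrap CIs (default 2000 replicates,
mandatory seed).  Resampling honours the paired design — a drawn case
contributes both of its condition ratings.  Fixed-reader mode keeps every
original reader and resamples cases (conclusions apply to these readers);
random-reader mode first resamples readers with replacement, then cases
(conclusions generalise to a reader population; intervals are wider
whenever between-reader variance is present).  A difference is declared
significant when the 95% CI excludes 0.5.  Measured over thousands of
simulated null studies at the default design, the fixed-reader interval
covers the true AUC of 0.5 about 94% of the time (individual 500-study
batches scatter by a couple of points around that).  With ten questions tested per
study at that per-question error rate, a handful of false positives per
*family* of questions is expected under the null; the pipeline reports
per-question intervals and leaves multiplicity control to the analyst.

## Dose accounting

Effective dose is `k · DLP` with the adult-chest coefficient
k = 0.015 mSv/(mGy·cm) by default (configurable; coefficients vary by
publication and tube voltage).  Protocol summaries report mean/min/max of
CTDIvol, DLP and effective dose, and the ratio of mean effective doses
between protocols.  The default study places the full-dose arm at a mean
DLP of 166.7 mGy·cm (2.5 mSv) and the ultra-low-dose (ULD) arm at
3.33 mGy·cm (0.05 mSv, 2% of full dose — a chest-radiograph-level dose).

## The default six-arm study

`run_study` crosses two protocols with three reconstruction surrogates:

| arm | noise shape | σ_ref (HU) | anatomy blur | edge filter |
|---|---|---|---|---|
| `asirv` | sharp_kernel | 40 | 0.4 mm | — |
| `dlir` | smooth_kernel | 15 | 0.8 mm | — |
| `dlir_e2` | smooth_kernel | 15 | 0.8 mm | gain 1.0, 1.5 mm |

The ULD protocol applies dose_factor 0.133 (noise × ≈2.74, the ratio of
the protocols' noise indices 85/31).  Observer studies compare `dlir`
against `asirv` (latent shift 0.6 at full dose, 1.2 at ULD — the
deep-learning arm helps more where noise is worse) and `dlir_e2` against
`dlir` (shift 0, no systematic difference).  25 patients are simulated as
independent noise realisations of the shared anatomy; 20 slices per
examination.  All stage seeds derive from one global seed by stable
hashing of stage names, so adding a stage never perturbs existing
streams and repeated runs are byte-identical.

These defaults reproduce the expected qualitative pattern: high-frequency
PS largest for the sharp-kernel arm and larger with edge enhancement than
without; CNR higher in the low-noise arms for essentially every patient
(paired t-test p < 0.05); vessel-profile peaks ordered sharp kernel >
edge-enhanced > smooth; random-reader CIs wider than fixed-reader.

## What the synthetic data does not show

The phantom is piecewise-constant, identical across slices and patients,
and noise is stationary, Gaussian and independent of the anatomy — none
of which is true of patient images reconstructed with non-linear
(iterative or deep-learning) algorithms, where noise and resolution are
local and contrast-dependent.  Passing tests therefore demonstrate that
the *measurement machinery* is correct and that the study design has the
claimed operating characteristics; they do not validate any vendor
reconstruction, and the magnitudes of synthetic CNR differences or AUCs
are properties of the chosen defaults, not predictions for clinical data.
The edge-enhancement surrogate is generic unsharp masking; its gain and
radius are free parameters, not calibrated to any proprietary filter.

## Problem sizes used in validation

Validation runs use sizes chosen to make Monte-Carlo tolerances sharp at
desk scale: 20-slice stacks for Parseval closure, 80 slices at 128 px for
the generator round trip, 2000 rating pairs for closed-form AUC recovery,
500 simulated studies for CI coverage, and the full default study
(25 patients × 6 arms, 512 px, 20 slices, 2000 bootstrap replicates) for
the directional checks.
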