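# Methods

## Signal model of the phantom

A phantom subject is a 64×64 grid (matching a typical single-slice ASL
matrix) holding an axis-aligned elliptical "brain" (semi-axes 24×18 px,
~1356 px, a third of the grid) and, inside it, a dorsal cortical band — the
shell of the ellipse with normalized radius in [0.65, 0.92), upper half
only (~288 px, ~21 % of the brain) — standing in for somatosensory/motor
cortex. Every frame is

    control(p) = anatomy + s(p) + ε,      labeled(p) = anatomy + ε,

with independent ε ~ N(0, σ²) per pixel per frame, and

    s(p) = b · (1 + f · (g_glob(c) + g_roi(c)·[p ∈ ROI]))   inside the brain,
    s(p) = 0                                                 outside,

where `b` is the baseline perfusion amplitude, `c` the CO₂ condition,
`f ∈ [0,1]` the stress attenuation factor, `g_glob` the brain-wide
fractional gain and `g_roi` the extra ROI gain. The additive form is the
simplest model for which the control-minus-labeled subtraction recovers
`s(p)` exactly in the noiseless limit, so ground truth is analytically
known at every pipeline stage. Anatomy (static tissue signal) is present in
both frame types and cancels in the subtraction.

Noise is Gaussian, not Rician: the pipeline operates on subtracted
magnitudes riding on a large static offset (anatomy ≫ σ), the regime in
which the Gaussian approximation to MRI magnitude noise is standard.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid_size | 64 | px | single-slice ASL matrix size |
| baseline_perfusion `b` | 100 | a.u. | fixes the intensity scale |
| anatomy_level | 500 | a.u. | static tissue ≫ noise, cancels in subtraction |
| g_glob (7–20 % CO₂) | 0.15 | — | whole-slice CBF increase of 15 % over baseline |
| g_roi (7–20 % CO₂) | 0.35 | — | total ROI increase 0.15+0.35 = 50 % |
| g (0 %, post-removal) | 0 | — | response is transient; gains return to zero |
| stress_factor `f` | 1.0 / 0.2 | — | unstressed / stressed group defaults |
| noise_sd σ | 20 | a.u. per frame | see below |
| sessions per concentration | 4 | — | study design |
| pairs per session | 8 + 8 | — | study design |
| subjects per group | 6 | — | study design |

The dose response is flat across the non-zero concentrations (no
dose-dependent differences are modeled), so a single gain value serves
7–20 %. The post-removal condition returns to zero gain by default for
both groups; a per-group gain override in `ExperimentDesign` can inject a
residual post-removal response as an emulation knob.

**Choice of σ = 20 a.u.** The per-condition activation map, built from 4
session maps of 8+8 frames, then carries noise of SD
σ·√2/(4·b) ≈ 0.071 in fractional units. Against the 2×RMS threshold this
makes the regime non-trivial in exactly the intended sense: ROI pixels
(signal 0.50) are essentially always activated, non-ROI brain pixels
(0.15) mostly are not (the map RMS over the brain, dominated by the
ROI/non-ROI contrast plus noise, puts the threshold near 0.3), and under
the null a small Gaussian-tail fraction of pixels false-positives. Much
lower noise trivializes every threshold; much higher noise drowns the
global effect.

## Analysis pipeline

* **Session perfusion**: `mean(control) − mean(labeled)`, pixel-wise.
  Linear in frame intensities.
* **Condition perfusion**: arithmetic mean of the ≥1 replicate session
  maps (4 in the default design; any count is accepted for reduced
  designs). Refuses to average maps tagged with different conditions.
* **Brain demarcation**: intensity threshold on the baseline perfusion
  image. Default rule: 0.2 × robust maximum (99.5th percentile); absolute
  and Otsu thresholds are available. The resolved threshold is recorded on
  the mask. On a noiseless phantom the default recovers the brain ellipse
  exactly, since the subtracted baseline image is anatomy-free.
* **Activation map**: `(P_c − B)/B` on brain pixels with `B > ε`, where
  ε = 10⁻⁶ × robust max of the baseline — a pure division guard; pixels
  failing it are flagged invalid (NaN) and excluded from every downstream
  statistic rather than producing infinities.
* **z-map**: per pixel, the two-sample statistic
  `(mean_c − mean_b)/√(var_b/n_b + var_c/n_c)` over replicate session maps
  (sample variances, ddof = 1), with a `baseline-sd` variant
  `(mean_c − mean_b)/sd_b` selectable in the analysis config; the formula
  used is recorded in the output. Replicate session maps, not the 8
  within-session pairs, are the sampling unit: sessions are the
  independent repetitions of the measurement. Thresholding at z > 3 is
  one-sided and strict — only CBF increases count.
* **Quantification**: RMS noise is the population (divide-by-*n*) SD over
  the demarcated pixels. It is computed on the activation map by default
  (each quantified image carries its own noise estimate); a config switch
  computes it on the baseline map instead. Threshold = 2 × RMS, strict
  inequality ("more than the threshold"). Metrics: intensity = Σ activated
  values, area = count, intensity-per-pixel = intensity/area (default;
  config switch divides by total slice area instead, and the convention is
  labeled in the output), normalized area = area/slice area. All four are
  0 when nothing is activated.
* **Statistics**: mixed two-way ANOVA via `pingouin.mixed_anova`
  (cross-checked in the tests against an independently coded split-plot
  sums-of-squares computation), no sphericity correction by default
  (Greenhouse–Geisser available as a config option). Holm–Šidák
  (`statsmodels`, step-down 1−(1−p)^(m−i+1) with monotonicity) adjusts the
  per-concentration between-group t-tests, the family being the set of
  conditions compared. The removal contrast (20 % vs post-0 %) is a paired
  t-test per group, Šidák-adjusted with family = the within-group
  comparisons run (one per group). Identical samples (zero-variance
  differences) report p = 1 rather than NaN. α = 0.05 throughout.

## Numerical and format choices

* Frames are written as 16-bit unsigned TIFF after the affine quantization
  `stored = round(v/0.05)` (step 0.05 a.u., recorded in the manifest),
  making cohort output byte-identical across reruns of the same master
  seed and hashes meaningful. Derived maps are 32-bit float TIFF
  (lossless); metric tables are CSV with a fixed column order.
* Interleave order on disk is control-first by default; the convention is
  a config field because the acquisition order is not recoverable from the
  file. A mis-set convention flips the perfusion sign, so the reader warns
  whenever a session's mean control-minus-labeled difference is negative.
* Seeding: each (subject, condition, session) stream is derived via
  `SeedSequence(spec.seed, spawn_key=(crc32(condition), session_index))`,
  so sessions are independent, reproducible, and platform-stable; subject
  seeds derive from the design's master seed the same way.
* Boundary conventions are strict everywhere a threshold appears (z >
  cutoff, value > 2×RMS, baseline > ε).

## What the validation suite shows — and what it cannot

The test suite validates the pipeline on phantoms at specific problem
sizes, chosen to give tight Monte-Carlo precision at interactive runtimes:
effect-size recovery over 20 seeds (bias < 0.01 noiseless, < 0.03 at
default noise); null false-positive calibration over 20 seeds at 128
replicate sessions per condition; occlusion ordering over 50 cohorts of 6
subjects; removal-detection rates over 40 cohorts.

Two calibration subtleties are worth knowing:

* **The 2×RMS null tail is only asymptotically Gaussian.** Under the null,
  the activation map is a ratio of noisy quantities; dividing by the noisy
  baseline skews it right (skewness ≈ 4.2 × the baseline map's coefficient
  of variation). At the default 4 sessions the one-sided tail beyond 2×RMS
  is ≈ 3.2 %, not the Gaussian 2.3 %; the Gaussian value is reached as
  replicates grow (≈ 2.3 % at 128 sessions, where the calibration test
  operates). The same convergence-in-replicates caveat applies to the
  z > 3 tail, which at 4 + 4 replicates is a t-statistic with ~6 df and a
  far heavier tail.
* **Power saturates because subjects differ only by pixel noise.** The
  phantom injects no between-subject variability in gains, so subject-level
  metrics are extremely precise and paired/group tests detect even tiny
  residual effects with probability ~1. Consequently the
  stressed-vs-unstressed and removal contrasts are all-or-nothing: a
  detection-rate *difference* between attenuation levels only emerges at
  (near-)full occlusion, where the removal test's detection rate collapses
  to the false-positive rate. Real cohorts, with biological
  between-subject variance, sit in between; conclusions about statistical
  power on real data cannot be read off these phantoms, only the
  correctness of the arithmetic and the direction of the effects.

Other limitations, by construction: no acquisition physics (no Bloch
simulation, no inversion-efficiency or transit-time modeling), no CO₂
pharmacokinetics, no atlas-shaped ROI (the band is parameterized so ground
truth stays exact), Gaussian rather than Rician noise, no spatial
smoothing or cluster/multiplicity correction over pixels, and perfusion in
arbitrary units only — no absolute CBF quantification.
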