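# Methods

This note documents the models, conventions and numerical choices behind
`gazescene`, in the order data flow through the pipeline.

## Coordinate conventions

All analysis happens in degrees of visual angle with the origin at the
stimulus-image center, x rightward and y upward. Pixels are 0-based with
pixel centers at integer + 0.5, y downward (image convention); the px↔degree
conversion is linear per axis with a constant factor (image: 1668 px / 40.6°
horizontally, 828 px / 20.1° vertically). A tangent (spherical) correction is
deliberately omitted: stimulus extents are specified directly in degrees, and
at a 270 cm viewing distance the small-angle error at the image corner is
well below the measurement noise of mobile glasses.

## Scene mapping

The stimulus occupies an unknown quadrilateral of the scene-camera view, so
gaze is projected through a plane homography estimated from marker-corner
correspondences (normalized direct linear transform; total least squares for
more than four points; RMS reprojection residual reported). A homography is
defined up to scale and is stored normalized to `H[2,2] = 1`. When several
scene-camera frames supply estimates for one trial, the per-trial transform
is the elementwise median — a static map per trial. Whether per-sample
interpolation between 30 Hz camera frames would be preferable is an open
question of the recording technology; the median is a robust, reproducible
default. Samples projecting outside the image are retained but flagged;
blink samples propagate as missing.

## Event detection

Velocities are computed with the ±2-sample difference kernel

    v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2}) / (6 Δt),

which is exact for linear motion and suppresses sample-to-sample noise.
Missing samples split the series; segments shorter than five samples yield no
velocities. The noise scale per axis is the median-based robust SD

    σ = sqrt( median(v²) − median(v)² ),

using the *lower* median for even counts — the formula is sensitive to the
tie rule, so it is fixed explicitly. σ below 10⁻⁶ deg/s is substituted by
that epsilon and flagged degenerate (a constant-velocity trace carries no
noise information).

A sample is a saccade candidate when `(v_x/λσ_x)² + (v_y/λσ_y)² > 1`.
Defaults: λ = 5, minimum saccade duration 3 samples, minimum binocular
overlap 1 sample. These follow the published conventions of the
velocity-threshold algorithm family; they are configuration values, not
claimed to equal any particular study's settings. Thresholds are estimated
per trial and per eye because noise levels vary strongly across mobile
recordings. Binocular saccades are overlapping monocular detections; event
boundaries are the union of the overlapping intervals, and unions that touch
are merged. Saccade amplitude is the start-to-end displacement of the
binocular-averaged position. Fixations are the complement intervals; their
dispersion statistic is the 2D positional SD `sqrt(var_x + var_y)`
(population variances, so a one-sample fixation has SD 0).

The smoothing kernel anticipates sharp velocity onsets by up to two samples;
with smooth (raised-cosine) saccade profiles and realistic noise the detected
onset is within one sample of the true onset for ≥ 95 % of saccades, which
the test suite verifies against the generator's ground truth.

## Preprocessing

Exclusion rules, with defaults: blinks; fixations shorter than 33 ms (four
samples at 120 Hz) or lasting 1000 ms or longer (the upper bound is
inclusive); fixations whose 2D SD exceeds 15× the median 2D SD of **all**
fixations in the dataset (pooled across trials, computed before any
removal); saccades strictly larger than 25°. Each critical event takes its
immediately preceding and succeeding events with it. Neighbor propagation is
single-step: all critical events are marked against the original sequence
first, then neighbors are marked, so neighbors-of-neighbors survive unless
independently critical and the outcome is order-independent. Adjacent blinks
do not cascade; this is a documented choice where the convention is
ambiguous. The ledger records every removal with its rule, threshold and
observed value, and `len(input) = len(kept) + len(ledger)` is a tested
invariant.

Trials fail the pre-image fixation check when any valid binocular sample in
the final 200 ms before image onset lies more than 2° from the cross; such
trials are dropped before event filtering. The first fixation of each trial
(on the cross) is excluded from analysis tables, guarded by an idempotence
marker. Start-position balancing retains, for each of the 15 cross
positions, the minimum count of that position across conditions (uniform
random subsampling, seeded); the resulting position × condition count table
has constant rows regardless of seed.

## Gaze statistics

Durations and amplitudes are natural-log transformed (the base only rescales
coefficients; natural log is fixed for reproducibility). Time bins are
half-open and a fixation belongs to the bin containing its onset — stated to
avoid double counting; a fixation overlapping the 2000 ms analysis boundary
is included iff its onset precedes it.

The fixation-density entropy uses a 128×128 grid covering the image exactly.
The density is unweighted (one count per fixation, not duration-weighted);
off-image fixations are excluded from the grid but retained for the distance
measure, where distance-to-center is defined regardless. Empty cells
contribute zero (`0·log 0 := 0`); the entropy ranges from 0 to
`log₂(128²) = 14` bits and is computed per image aggregated over subjects,
which is why the entropy model carries no subject variance component. The
model response is `exp(S)` with the natural exponential — the transform's
base is not fully determined by convention, so base e is documented here.

Amplitude densities use a Gaussian kernel with bandwidth equal to half the
sample SD, implemented as an explicit mixture so that a zero-SD sample
degenerates gracefully to an epsilon-bandwidth bump.

The uniform reference for the central fixation bias is the Monte-Carlo mean
distance to the center of the 40.6° × 20.1° rectangle (≈ 12°, standard error
reported). Within-subject confidence intervals subtract each subject's mean,
add the grand mean, and inflate the t-based half-width by `sqrt(C/(C−1))`
for C conditions.

## Inference

Contrasts are coded ±½ within the compared sets (0 elsewhere) so that on a
balanced design each coefficient equals the named difference of condition
means; the interaction column is the elementwise product of the Task and
Body columns, which already estimates the difference of differences. The
exact coding magnitude used by any particular published analysis is
generally not recoverable from reported coefficients alone; ±½ is this
package's documented convention.

Models are estimated by maximum likelihood. Crossed subject/image random
intercepts (and the optional uncorrelated image slope) are expressed as
variance components of `statsmodels.MixedLM` on a single grouping block;
optimizers are tried in the order lbfgs, bfgs, powell, and a fit that never
converges raises an error carrying the optimizer trace. Variance estimates
within 10⁻⁶ of zero are flagged as boundary fits, not errors; a grouping
factor with fewer than two levels is dropped to the boundary, so a
single-subject fit equals the image-only model. With no random structure the
ML fit is ordinary least squares, which doubles as an oracle in the tests.
Inference is Wald `t = M/SE` with |t| > 2 flagged by convention; no
degrees-of-freedom correction (Satterthwaite/Kenward-Roger) is attempted.
Covariates of the distance model — the start-position distance centered at
its mean and scaled by its SD, and the standardized log fixation ordinal —
are standardized on the analysis subset after balancing.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the visual content of scenes:

- **Trials**: 8 s at 120 Hz; the trial starts with a fixation at one of the
  15 cross positions (3 vertical at 25/50/75 % × 5 horizontal at
  20/35/50/65/80 % of the projection screen).
- **Fixation durations**: log-normal, μ = 5.46 log-ms, σ = 0.35, giving a
  ~250 ms arithmetic mean — the regime typical of natural scene viewing.
- **Saccades**: amplitudes log-normal moment-matched to mean 6°, SD 3°;
  duration 21 + 2.2·amplitude ms (a main-sequence-like affine law) with a
  symmetric raised-cosine velocity pulse. Any smooth unimodal profile would
  do; this one is fixed and documented.
- **Target selection**: with probability a(t) the next target is drawn from
  a center-anchored Gaussian (SDs 6° × 3.5°); otherwise the gaze takes an
  amplitude-directed step in a uniform direction, reflected at the image
  boundary. The anchor probability decays from 0.6 to a floor of 0.25 with a
  1000 ms half-life, reproducing an early-strong central fixation bias.
  Because reflection preserves uniform measure, the anchor-free walk mixes
  toward the uniform distribution, whose mean distance-to-center is the 12°
  reference — a tested property.
- **Noise and blinks**: independent per-eye white noise, SD 0.2° per axis —
  representative of mobile eye-tracking glasses precision (mobile signals
  are noisier than desktop recordings); an optional fixed horizontal
  disparity (default 0°); blinks as a Poisson process (0.1/s) with
  log-normal durations (median 150 ms), flagged per sample with missing
  positions.
- **Effects**: condition effects are additive shifts on log-duration,
  log-amplitude and anchor probability per factor level; subject and image
  random intercepts (defaults 0.1 on log-duration, 0.05 on log-amplitude)
  are drawn once per unit. All randomness flows from one root seed via
  `SeedSequence` spawn keys, so any trial is reproducible in isolation.

What the generator does **not** emulate: image-content-driven salience,
smooth pursuit, eye/head movement decomposition, calibration drift, or
temporally correlated tracker noise. Passing tests therefore demonstrate
that the pipeline recovers the statistical structure it models — not that
real recordings satisfy that structure.

## Problem sizes in the test suite

The suite favors sizes that make Monte-Carlo conclusions stable while
keeping a full run in tens of seconds: 200 seeded trials for detection
recovery, 200 replicates of a 30-subject × 30-image grid for mixed-model
coverage, a 10 × 10 experiment for the end-to-end effect-recovery test, and
10⁶ points for the uniform-distance reference. These are the package's
chosen test conditions; larger runs only narrow the Monte-Carlo error.

## Known limitations

- The homography stage assumes marker correspondences are given; corner
  detection from video is out of scope, as is lens-distortion correction.
- Velocity thresholds assume approximately stationary noise within a trial;
  slow drifts inflate σ and can mask small saccades.
- The entropy statistic is sample-size dependent (few fixations cannot fill
  the grid), so entropy comparisons are only meaningful at matched counts —
  the per-image aggregation handles this for balanced designs.
- Wald t-values without degrees-of-freedom correction are anticonservative
  for few groups; with ~30 subjects/images the |t| > 2 convention is
  adequate, below that it is not.
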