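# Methods

This note documents the models, numerical choices and limitations behind
`lungesym`.  All displacement quantities are in millimetres, stride times in
milliseconds, angles in degrees; sampling is nominally 100 Hz.

## Signal model and the synthetic generator

At trot, midline landmarks (poll, withers, sacrum) oscillate vertically
twice per stride — once per diagonal step — while each tuber coxae shows one
dominant oscillation per stride, rising ("hiking") during the stance of the
contralateral hind limb.  The generator builds each landmark's displacement
as a chain of quintic smoothstep arcs between prescribed extrema:

    z(t) = v0 + (v1 − v0) · (6τ⁵ − 15τ⁴ + 10τ³),   τ = (t − t0)/(t1 − t0)

Each arc is monotone with zero velocity *and* zero acceleration at both
ends, so the prescribed extrema are attained exactly and the analytic second
derivative is continuous.  Injected left/right differences of minima,
maxima, tuber-coxae hike and range of motion enter the extremum values
directly, which makes the ground truth analytically invertible.  Two
consequences of this construction are worth stating:

* With upward amplitude defined as a maximum minus its immediately
  preceding minimum, the midline upward-amplitude asymmetry is identically
  `asym_max − asym_min`; it cannot be injected independently, and
  `TrotParams` validates any explicitly supplied value against that
  identity.
* Because the arcs are quartically flat at their extrema, sampling an
  off-grid extremum at 100 Hz clips it by well under 0.05 mm; no grid
  alignment of extrema is needed.

The sensor-frame acceleration is the analytic second derivative plus
gravity, rotated through a fixed known orientation (roll/pitch/yaw Euler
angles, yaw–pitch–roll composition, pitch positive nose-up in the z-up
horse frame).  The acceleration spectrum of a piecewise-polynomial track
decays only ~1/f², so pointwise sampling would alias high harmonics onto
the stride harmonics (with 75 samples per stride the folding is exactly
resonant and corrupts recovered asymmetries by ~1 mm).  The generator
therefore samples the way an IMU front end does: the analytic acceleration
is evaluated at 8× oversampling, anti-alias filtered and decimated
(`scipy.signal.decimate`, FIR, zero-phase).

**Noise.**  `noise_sd` adds white Gaussian noise to all three acceleration
channels, scaled as displacement-equivalent millimetres at the stride
frequency: `sd_acc = noise_sd · (2π/stride_time)²` (SI units).  The stride
frequency is the band that carries the left/right asymmetry information
(asymmetries are odd-harmonic content), so this scale makes "2 mm of noise"
mean 2 mm of disturbance where it matters.  The default study condition is
`noise_sd = 2 mm` with 5% uniform stride-time jitter.

**Circle modulation.**  A horse on a circle of radius r at speed v leans
inward by θ = arctan(v²/(g·r)).  The induced movement asymmetry is modelled
as linear in the lean angle with gain `lean_gain` (default 0.8 mm/deg, a
free parameter — no quantitative slope is established for this relation),
directed toward the inside of the circle: the full offset Δ = lean_gain·θ
is added to the minima differences, hike and range-of-motion differences
and Δ/2 to the maxima differences, so all eleven indices respond and
left/right-rein modulations mirror exactly.  The default circle radius is
7.5 m (a 15 m lunging circle) with slow/fast trot at 3 and 4 m/s.

**Study-level generator.**  `simulate_study` draws condition tables
directly from the additive model the statistics layer assumes: per
parameter, value = baseline + horse intercept (SD `horse_sd`) +
surface shift (hard − soft) + speed shift (fast − slow) + circle term +
residual, generated in the frame of the horse's own asymmetry direction and
flipped to the raw left/right frame by a per-horse, per-parameter random
side (P(left-sided) = 0.5 by default, emulating a mixed clinical
population; the all-zero-effects identity `record = baseline` holds when
sides are fixed left).  Defaults: 27 horses, 12 conditions (2 surfaces ×
2 speeds × 3 directions), baselines of ≈5–18 mm matching clinically
asymmetric horses, horse SD 3 mm, residual SD 2 mm, surface effect 2 mm,
no intrinsic speed effect (speed acts through the circle term, which is the
mechanism under test).  Stride time has its own additive model: grand mean
772 ms, fast − slow = −38 ms, hard − soft = −14 ms, straight −25 ms vs
lunge +12.5 ms (both reins equal — equal rein speeds are the design's
premise), horse SD 20 ms, residual 10 ms.

One integer seed drives everything; per-horse and per-landmark streams are
split deterministically (`numpy` `SeedSequence`), so outputs are
bit-reproducible and traces of one condition share stride timing across
landmarks.

## Kinematics

**Rotation.**  Orientation angles define the per-sample rotation into the
right-handed horse frame (x forward, y left, z up); gravity (9.81 m/s²) is
subtracted after alignment.

**Double integration.**  Vertical acceleration is high-pass filtered,
integrated (cumulative trapezoid), high-passed again, integrated, and the
displacement is high-passed once more and mean-centred.  The filter is a
fourth-order zero-phase Butterworth (forward–backward `sosfiltfilt`) with
cutoff 0.5 × the stride-frequency hint — half an octave below the stride
frequency and two octaves below the step frequency, so the asymmetry-
carrying band passes essentially unattenuated.  The third (displacement)
pass exists because the second integration re-accumulates sub-cutoff
remnants of the filtered velocity into a slow wander.  The cascade still
leaves edge transients that decay over roughly three strides per record
end; the pipeline discards the outermost three strides of each record
before feature extraction, and record durations are chosen so that at least
15 clean strides remain (the hard floor per condition; data collection
conventionally aims at 25–30).

**Stride segmentation.**  The step period is estimated from the first
autocorrelation peak of the (midline) displacement; the stride period is
twice that, because midline landmarks oscillate twice per stride and a
near-symmetric signal's autocorrelation cannot distinguish the two steps.
Boundaries are placed on every other displacement minimum, phase-locked to
the deepest minimum so the within-cycle landmark is consistent.  Strides
whose duration deviates more than 25% from a running median (window 7) are
discarded as non-steady-state; the 25% bound and the windowed median are
package choices — steady-state trimming needs *some* rule and medians keep
a single bad stride from shifting the reference.  A record of n full
strides yields n − 1 fully bounded ones (boundary minima at the record
edges are not detectable).

**Features and attribution.**  Per stride, each midline landmark must show
exactly two minima, two maxima and two upward amplitudes (maximum minus the
immediately preceding minimum — the within-stride pairing is an explicit
package choice); strides without that pattern are dropped and counted.
Features are attributed to the left or right step by the hind-stance labels:
within each half-stride the tuber coxae that rises more marks the
contralateral hind stance.  Synthetic traces also carry exact stance labels
so segmentation and attribution can be validated independently.

## Indices, medians, normalization

All eleven indices are computed left-associated minus right-associated, so
a positive value is the pattern conventionally attributed to the left limb.
This one fixed convention (rather than per-parameter conventions from force-
plate literature) is sufficient because every downstream step — sign
normalization, inside/outside labeling, averaging, modelling — depends only
on its consistent use.  Conditions are summarised by medians across strides
(robust to residual transient strides), with stride count recorded.

Normalization is two-step, per horse and per parameter independently:
(1) if the mean of the straight-line values is negative, all values of that
parameter for that horse are inverted (an exactly zero mean — not covered
by the rule — maps to "no inversion" with a warning); (2) the left/right
rein labels are replaced by inside/outside relative to the preexisting
side, where a positive straight-line mean under the left-minus-right
convention means left-sided.  Average-rein values are the arithmetic means
of the normalized per-condition *medians* of inside and outside rein;
cells missing one rein produce no average row and are counted.  Horses
without any straight-line assessment are rejected (inclusion rule).
Screening flags use |value| > 6 mm for head and > 3 mm for pelvic
parameters (strict inequalities, configurable).

## Statistics

All SDs use the n − 1 denominator; significance is α = 0.05.

* **Intra-horse SD** pools, across horses with ≥ 2 straight-line
  conditions, the deviations of each straight-line value from its horse's
  mean, and reports a single SD (per-horse deviations are also exposed).
* **Limits of agreement**: differences straight − average per matched
  horse × surface × speed cell; bias = mean, SD (n − 1), band = 2·SD.
* **Trend lines**: ordinary least squares of rein values on straight-line
  values; R² is the squared Pearson correlation; a constant-y input is
  reported as slope 0, R² 0.
* **Mixed models**: `response = fixed main effects + horse intercept +
  residual`, fitted by REML (statsmodels `MixedLM`).  Fixed-factor
  p-values are Wald F tests using residual degrees of freedom
  (n − k_fixed); the original analysis software's degrees-of-freedom
  method is not knowable from outside, so this choice is encapsulated and
  documented rather than hidden.  Estimated marginal means are model
  predictions averaged over a fully crossed (balanced) grid of the other
  fixed factors, the classical marginal-means definition.  Pairwise
  contrasts between the three movement directions are Wald t tests with
  Bonferroni adjustment (p × 3, capped at 1); `bonferroni_adjust` is
  exactly min(1, p·m).  Non-convergence and singular (zero) random-
  intercept variance are flagged on the result, never silent; an OLS refit
  on singular fits is available by explicit option.  A constant response
  short-circuits to a degenerate result (p = 1, EMMs equal) rather than
  asking REML to estimate two variances from none.  Residuals are exposed
  and can be written as histograms for the conventional visual normality
  check; no formal test is imposed.

## What the tests do and do not show

The synthetic generator reproduces the statistical *structure* the analysis
assumes — controllable asymmetries, mirror-symmetric circle effects,
horse-level random intercepts, additive surface/speed shifts, white sensor
noise — with exactly known ground truth.  Passing tests therefore
demonstrate that the processing chain recovers what it claims to recover
and that the statistical machinery is calibrated (surface-effect bias
< 0.2 mm and 5% empirical size at 200 replicates, 30 horses).  They do not
validate the segmentation or integration protocols against real IMU data:
real trot signals contain transient gait irregularities, soft-tissue and
mounting artefacts, orientation drift and dropped packets that the
generator deliberately omits, and the lean-to-asymmetry gain is a free
parameter, not an estimate of the physiological slope.  Problem sizes in
the test suite (records of ~24–28 s giving 22–31 clean strides; 100–200
replicate studies for the property and calibration checks) were chosen as
the smallest sizes at which medians and replicate rates are stable.

Normalization by an estimated sign has a known attenuation property: horses
whose straight-line mean is misclassified (possible when the true baseline
is small relative to the horse SD) contribute with flipped effect signs,
biasing pooled fixed-effect estimates toward zero.  The calibration checks
therefore run with fixed sides; the study-level analyses inherit whatever
attenuation the normalization implies, exactly as a real analysis would.
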