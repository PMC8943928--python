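# Methods

This note records the models, conventions and design decisions behind
`adlkin`, in the spirit of a statistical software methods appendix: what
is computed, under which assumptions, and where genuinely open choices
were settled.

## Signal model and preprocessing

A wrist accelerometer at rest measures the gravity vector; during
manual activity, movement accelerations superpose on it. The package
reduces each tri-axial recording to a scalar magnitude chain:

1. **Magnitude** — per-sample Euclidean norm of (ax, ay, az), m/s².
2. **Gravity removal** — the standard constant 9.81 m/s² is subtracted
   and the result rectified (absolute value). No orientation estimate
   or sensor fusion is attempted; the constant-subtraction model is
   exact when the movement acceleration is parallel to gravity and
   biased low otherwise, an error that grows during low horizontal
   accelerations. The synthetic generator's orientation wobble exists
   precisely to exercise this term.
3. **Loess smoothing** — locally weighted polynomial regression of
   degree 2 with tricube weights over a 420 ms span. The span in
   samples is `round(window · fs)` rounded up to the nearest odd count
   so windows are centered (43 samples at 100 Hz). At the series
   boundaries windows are truncated; no padding or reflection is used.
   Rectification order is subtract → absolute value → smooth, so no
   negative values enter the local fits; residual negatives produced by
   the quadratic fits near sharp transitions are clipped at zero.

Interior points of a fixed-span loess smoother share one set of
regressor offsets and weights, so the estimate reduces to a single
convolution kernel (a tricube-weighted Savitzky–Golay filter); boundary
points fall back to explicit weighted least squares. The test suite
checks this fast path against a literal per-window fit.

Irregular timestamps (more than 1% of intervals deviating over 10% from
nominal) are linearly interpolated onto the nominal grid, with a
warning.

Tunable parameters: `gravity` (9.81 m/s²), `smooth_window` (0.420 s),
`loess_degree` (2), `rectify` (on). The window matches the smartwatch
analyses this package operationalizes; degree 2 with tricube weights is
the classic local-regression choice and reproduces locally quadratic
burst profiles without attenuation.

## Kinematic parameters

All nine parameters are defined on the preprocessed magnitude and one
peak-detection pass. Conventions that the definitions leave open were
fixed as follows:

* **Peak universe.** Every strict local maximum counts, with no height
  floor. RATIO divides prominent peaks by *all* peaks, so the
  denominator must include noise peaks; imposing a floor would make
  RATIO ill-defined. Plateaus count once, at their first sample.
  Prominence uses the standard topographic definition with the series
  edges as terrain boundaries.
* **Thresholds.** RA uses a strict `> 0.2 m/s²` (activity must
  *exceed* the threshold); RATIO uses an inclusive `≥ 0.2 m/s²`
  (a *minimum* prominence). Both thresholds are configurable.
* **SUM and APS** are per-second sums, `Σa²/TD` (m²/s⁵) and `Σa/TD`
  (m/s³) — equivalently mean(a²)·fs and mean(a)·fs. Among the
  normalizations consistent with a "temporal" reading, this is the one
  that reproduces the printed units and the numeric scale (tens of
  m²/s⁵ and m/s³) of published cohort tables; it is stated prominently
  because per-sample means would differ by a factor of the sample rate.
* **STD** is the sample (n−1) standard deviation; **MAX95** uses
  linear interpolation between order statistics at position `(n−1)p`.
* **Undefined values** (STD with fewer than two peaks, peak means
  without peaks) are reported as NaN and propagate as missing — never
  as zero. Statistics downstream are complete-case per comparison.
* No minimum peak separation is imposed; none is part of the
  parameter definitions.

Useful invariants (all tested): scaling the signal by k scales
STD/MPA/MAX95/APS by k and SUM by k², leaves TD/PPS unchanged and moves
RA monotonically; concatenating a trial with itself doubles TD and
leaves the rate- and height-based parameters invariant.

## Frailty scoring

The adapted Fried phenotype enters as five adjudicated booleans
(unintentional weight loss, exhaustion, low physical activity, low grip
strength, slow walking speed). The score is their count; category R at
0, P at 1–2, F at 3 and above. The clinical operationalization of each
criterion (grip-strength cutoffs by sex and BMI, walk-time cutoffs) is
deliberately out of scope: the pipeline consumes outcomes, not raw
clinical measurements, and never imputes a missing criterion.

## Statistics

* **Group comparisons.** Classical one-way ANOVA per parameter with
  partial η² = SSB/(SSB+SSW), and Tukey HSD post hoc tests on the
  studentized range distribution with pairwise Cohen's d (pooled-SD
  denominator). Tests are two-sided at α = 0.05; no multiplicity
  correction is applied across the nine parameters, so per-parameter
  p-values must be read descriptively.
* **Multivariate group test.** The joint null of no group effect on
  any parameter is tested by permutation: the statistic is the sum of
  per-parameter ANOVA F values (computed on standardized columns; F is
  affine-invariant, standardization only keeps the statistic's scale
  readable) and its null distribution comes from shuffling group
  labels, with the add-one estimate p = (1 + #{null ≥ obs})/(1 + B).
  A permutation test was chosen over parametric MANOVA because the
  cohorts of interest are small (tens of participants) and the feature
  distributions are skewed; the test is exact under exchangeability
  and its type-I error is verified by simulation in the test suite.
* **Inter-task correlations.** Pearson r between the TEA and GARDEN
  value of each parameter, complete pairs only, at least three pairs.
* **Stepwise regression.** Forward selection of predictors of the 0–5
  frailty score: at each step the candidate with the smallest partial
  p-value enters if p ≤ 0.05 and no variance inflation factor of the
  resulting design reaches 5.0; after each entry, predictors whose
  p-value has risen to ≥ 0.10 are removed. Coefficients are reported
  standardized (fit on z-scored variables) together with R², adjusted
  R², the model F-test p-value and per-predictor VIFs. The 0.05/0.10
  entry/removal pair is the long-standing default of mainstream
  statistics packages; with nine candidate predictors and no true
  signal the expected chance of any first-step entry is
  1 − 0.95⁹ ≈ 0.37, which the suite verifies, so selected models on
  small cohorts should be treated as descriptive.

## Synthetic data generator

The generator emulates the structure of wrist-magnitude signals during
standardized kitchen and gardening tasks, with full ground truth.

**Model.** A trial of Gaussian-drawn duration is partitioned into
active phases and pauses by an alternating-renewal walk (exponential
segment lengths, mean spontaneous pause 2 s) targeting a per-cell pause
fraction. Tea-making trials additionally carry a fixed 60 s pause with
onset at 40 s, standing for the standardized water-boiling wait.
Within active phases, movement bursts occur quasi-rhythmically: centers
advance by gamma-jittered gaps (shape 6, mean 1/`burst_rate`), because
reach–grasp sequences are roughly periodic rather than memoryless;
burst supports are kept strictly inside their active phase, so pauses
contain only noise and orientation drift. Each burst contributes a
truncated-Gaussian bell envelope (sd = duration/4, support ±2 sd,
renormalized to peak exactly at the drawn amplitude). The scalar
magnitude is `g + Σ envelopes + drift + noise`, where drift is
`g·(1 − cos θ(t))` with θ a 0.1 Hz sinusoidal tilt of amplitude
`orientation_wobble`, and noise is white Gaussian (`noise_sd`). The
magnitude is then distributed onto three axes along a unit direction
blending the tilted gravity axis with random per-burst directions
(uniform on the sphere), so the downstream norm step is nondegenerate
and recovers the constructed magnitude exactly.

**Between-participant heterogeneity.** Each participant carries a
lognormal movement-vigor multiplier (mean 1, log-sd
`participant_sd` = 0.18) applied to burst amplitudes and shared across
both tasks. Without it, all participants of a group are statistically
identical, group effect sizes become implausibly large and inter-task
correlations vanish; with it, within-group feature spreads, ANOVA
effect sizes (partial η² ≈ 0.2–0.4) and the strong inter-task
correlations of the intensity-type parameters all land in the range
reported for real frail-elderly cohorts.

**Calibration.** The shipped `default_config()` fixes one parameter
cell per frailty group × task. Cells were calibrated so that, at 30
recordings per cell, cohort means of TD, RA and MPA fall within ±20%
of the published group×task cell means (TEA TD 137/150/147 s,
RA 0.40/0.44/0.51, MPA 0.39/0.38/0.38; GARDEN TD 96/117/90 s,
RA 0.74/0.66/0.61, MPA 0.94/0.69/0.61 for R/P/F), with burst
amplitudes ordered robust > pre-frail > frail within each task and
GARDEN more intense than TEA. Trial-duration spreads are kept moderate
(sd ≈ 15–25% of the mean) so that 30-trial cells represent their means;
real cohorts include occasional extreme trials that small synthetic
cells cannot average out. Published tables constrain only means and
SDs of derived features, so this calibration is by construction
approximate: PPS and RATIO, which depend on fine noise structure, sit
below their published values and are not calibration targets.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: biomechanically realistic limb
trajectories, task-specific action sequences, gyroscope information,
bimanual coordination, sensor artifacts (clipping, dropped samples),
and any participant-level covariance beyond the single vigor
multiplier. Parameter-recovery results on synthetic cohorts demonstrate
the correctness and operating characteristics of the pipeline, not the
clinical validity of the measures.

## Numerical and reproducibility choices

* Randomness: every recording derives its stream from a
  `SeedSequence` over (seed, CRC32 of group, task and participant id);
  participant-level draws (frailty criteria, vigor) use separate
  streams keyed by participant only. Identical configuration and seed
  give bit-identical cohorts; recordings are independent of cohort
  composition.
* Trial durations are floored (5 s, or the fixed-pause end + 5 s) and
  rounded to whole samples; burst durations are floored at 0.15 s and
  amplitudes at 0.05 m/s².
* Degenerate inputs: series shorter than 3 samples yield an empty peak
  set with a warning; empty signals have TD 0; ANOVA refuses groups
  with fewer than 2 observations; the permutation test refuses
  B < 1 and warns below 100.
* Problem sizes in the shipped tests: oracle equivalence uses
  exhaustive enumeration to length 12 over a 3-value alphabet and 1000
  random signals; operating characteristics use 200 null cohorts at
  2000 permutations, 1000 stepwise cohorts at n = 27, and five seeds of
  30-recordings-per-cell calibration cohorts. The stepwise recovery
  simulation pins the planted predictor's in-sample R² at exactly 0.25
  (residuals orthogonalized in sample) so the check isolates selection
  behavior rather than sampling variation of the effect itself.

## Known limitations

* Constant-gravity subtraction biases the magnitude low during purely
  horizontal accelerations; the wobble term only exercises, not
  corrects, this error.
* The loess edge policy (truncated windows) leaves the first and last
  ~0.2 s slightly less smoothed; features of very short trials are
  therefore more edge-sensitive.
* The stepwise procedure inherits the known optimism of selection on
  small samples; reported R² values are not shrinkage-corrected.
* Calibration targets cover TD, RA and MPA; the remaining six
  parameters track the right orderings but not necessarily the
  published magnitudes.
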