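# adlkin

Wrist-accelerometry kinematics of activities of daily living (ADL) for
frailty research.

Frail and pre-frail elderly people perform everyday manual tasks —
making tea, repotting a plant — differently from robust ones: their
movements are less intense, less variable in amplitude, and broken by
more pauses. `adlkin` turns raw 100 Hz tri-axial acceleration from a
wrist-worn smartwatch into nine kinematic parameters that capture these
differences, scores the adapted Fried frailty phenotype, and runs the
group-level statistics that relate the two. A synthetic signal
generator with known ground truth makes the whole chain testable
without any clinical recordings.

The package is for movement scientists and gerontology researchers who
want a reproducible, scriptable version of this analysis — either to
apply it to their own smartwatch recordings or to study its behavior
under controlled synthetic conditions.

## The measures

A recording is reduced to a scalar magnitude signal
`a(t) = loess(| ‖a_xyz(t)‖ − g |)` (Euclidean norm, gravity
`g = 9.81 m/s²` subtracted as a constant, rectification, 420 ms local
quadratic regression with tricube weights). From `a(t)` and its local
maxima ("acceleration peaks") nine parameters are computed:

| group      | parameter | definition | unit |
|------------|-----------|------------|------|
| activity   | TD    | trial duration | s |
| activity   | RA    | fraction of samples with a > 0.2 m/s² | – |
| agility    | STD   | SD of peak heights (n−1) | m/s² |
| smoothness | PPS   | peaks per second | 1/s |
| smoothness | RATIO | share of peaks with prominence ≥ 0.2 m/s² | – |
| energy     | SUM   | Σ a² / TD | m²/s⁵ |
| energy     | APS   | Σ a / TD | m/s³ |
| intensity  | MPA   | mean peak height | m/s² |
| intensity  | MAX95 | 95th percentile of peak heights | m/s² |

Frailty: five adapted Fried criteria (weight loss, exhaustion, low
physical activity, low grip strength, slow walking speed) give a 0–5
score; 0 = robust (R), 1–2 = pre-frail (P), ≥ 3 = frail (F).

Statistics: per-parameter one-way ANOVAs across R/P/F with partial η²
and Tukey HSD post hoc tests (Cohen's d), a permutation-based
multivariate group test (sum of per-parameter F statistics under group
label shuffles), Pearson inter-task correlations (task specificity),
and forward-stepwise multiple linear regression of the frailty score
(entry p ≤ 0.05, removal p ≥ 0.10, VIF < 5, standardized β).

## Worked example

Simulate a 27-person cohort (8 R / 13 P / 6 F, two tasks each) at the
shipped calibration and run the full analysis:

```sh
adlkin run --simulate --out demo --seed 1 --perm 2000 --verbose
```

The report (excerpt, GARDEN task):

```
--- group means (SD) by parameter, scope: GARDEN ---
param                  R               P               F         p   eta2p
TD         93.26 (17.30)  116.54 (19.16)   82.54 (21.41)    0.003*    0.39
RA          0.78 ( 0.04)    0.68 ( 0.07)    0.67 ( 0.09)    0.010*    0.32
STD         0.74 ( 0.08)    0.69 ( 0.11)    0.63 ( 0.10)    0.152     0.15
MPA         0.95 ( 0.13)    0.71 ( 0.20)    0.62 ( 0.13)    0.003*    0.38
MAX95       2.20 ( 0.21)    1.94 ( 0.37)    1.76 ( 0.26)    0.038*    0.24
multivariate permutation test: statistic=58.13, p=0.0020

--- stepwise MLR of frailty score, scope: TEA ---
R2=0.244 (adj 0.214), model p=0.0088
  PPS      beta_std= -0.494  VIF=1.00
```

Reading it: in the gardening task the robust group moves with higher
intensity (MPA 0.95 vs 0.62 m/s² for frail) and fewer pauses (RA 0.78
vs 0.67), the group effect is significant for several parameters
(p < 0.05, partial η² ≈ 0.2–0.4), and a single smoothness or agility
parameter suffices to explain ~20–50% of the variance in the 0–5
frailty score. Every output also lands as CSV (`features.csv`,
`group_comparisons.csv`, `correlations.csv`, `regression_<scope>.csv`)
plus a `run_log.json` with versions, seed and config hash; identical
seed and config reproduce every file byte for byte.

The CLI also exposes the stages separately (`adlkin simulate`,
`adlkin preprocess`, `adlkin extract`, `adlkin analyze`); the same
functionality is available as a library (`adlkin.preprocess`,
`adlkin.features`, `adlkin.frailty`, `adlkin.stats`,
`adlkin.synthetic`, `adlkin.pipeline`).

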