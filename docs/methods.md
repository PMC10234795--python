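# Methods

This note documents the models and procedures `move24` implements, the
defaults it ships, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Scope and data model

The package starts from calibrated epoch-level data: per participant, a
uniformly spaced series of ENMO (mg) and wrist z-angle (degrees),
typically at 5-s epochs over at least four days.  Raw-signal processing
(autocalibration, implausible-value screening, non-wear detection and
imputation) is upstream of this package and assumed done.  A
participant enters the analytical sample when they have complete
midnight-to-midnight days covering at least three weekdays and one
weekend day.  All per-day characteristics are averaged as a weighted
week, (5 × weekday mean + 2 × weekend mean) / 7; this weighting is
applied uniformly across the four metric families.  Metrics that are
inherently multi-day (the cosinor fit, IS, IV, and the average-profile
M10/L5) are computed once over all retained days.

## Time-use estimates

Waking epochs are classified by ENMO against youth non-dominant-wrist
cut-points: sedentary < 48 mg ≤ light < 201 mg ≤ moderate < 707 mg ≤
vigorous.  The cut-point value itself joins the higher category (48 mg
is light): the thresholds are described as the *upper* bound of
sedentary time and *lower* bounds of the activity intensities, which
leaves the boundary epoch ambiguous; lower-inclusive-for-the-higher-
category is the convention adopted here and tested.

Epochs inside a detected sleep-period window count as sleep.  A night's
window is attributed to the calendar day containing its onset, so a
night spanning midnight is not split; each day's waking parts are then
rescaled to fill 1440 − sleep minutes, which absorbs the mismatch
between a day's own morning tail and the next morning's without double
counting.  Every emitted composition sums to 1440 min.

## Sleep-period detection

The detector follows the heuristic family based on the distribution of
change in the z-angle.  Per noon-to-noon night: absolute successive
differences of the per-epoch z-angle are smoothed with a centred 5-min
rolling median; epochs below threshold form candidate rest segments;
segments ≥ 30 min separated by < 60 min are merged; the longest merged
block is the sleep-period window; above-threshold runs inside the
window lasting ≥ 1 min (debounce) are wake bouts.  The threshold is
15 × the night's 10th percentile of the smoothed values, capped at 5°
to prevent runaway thresholds on noisy nights — the cap is a safeguard
from the algorithm family, exposed as a parameter.  Windows longer than
12 h are flagged implausible rather than truncated.  Sleep duration is
window length minus wake-bout minutes; efficiency is duration as a
percentage of window length ("time in bed" is operationalised as the
detected window, since no separate bed-time sensor exists); onset is
reported in decimal hours with after-midnight onsets mapped above 24
(00:30 → 24.5) so nightly averages are meaningful.  The minimum
wake-bout length that counts as an awakening is a parameter (default
1 min), as definitions vary across devices and pipelines.

## Rest-activity rhythms

The extended cosinor is the anti-logistic transform of the cosine
curve, fitted by bounded nonlinear least squares (scipy trust-region
reflective) to 1-min means of log(ENMO + 1):

    Y(t) = min + A · G(cos(2π(t − φ)/24)),   G(r) = expit(β(r − α))

with minimum level *min*, amplitude *A* ≥ 0 (peak minus minimum),
acrophase φ (decimal hours), peak-width α ∈ [−1, 1] and steepness
β > 0.  The mesor is reported as min + A/2.  The fit multi-starts the
acrophase at 0, 6, 12 and 18 h and keeps the best residual sum of
squares; φ is reported modulo 24.  When the fitted curve explains less
than 5% of the signal variance the fit is flagged `flat`: amplitude is
then within the noise and the acrophase is unreliable.

IS and IV are computed on hourly means (the dominant convention; a
30-min basis is available via the `bin_minutes` argument):

    IS = n Σ_h (x̄_h − x̄)² / (p Σ_i (x_i − x̄)²)        ∈ [0, 1]
    IV = n Σ_{i≥2} (x_i − x_{i−1})² / ((n−1) Σ_i (x_i − x̄)²) ∈ [0, 2]

with p bins per day and n total bins; IS = 1 for perfectly repeating
days, IV → 2 for white noise.  Zero-variance series are flagged rather
than given a value.  M10 and L5 are the extreme circular rolling means
(600- and 300-min windows) of the average 24-h minute-level ENMO
profile, reported in mg with their start clock times; the average
profile is primary because day-level M10/L5 would mix rhythm timing
with day-to-day level shifts.

Average acceleration is the plain mean of ENMO per day, weighted-week
averaged.  The intensity gradient accumulates minutes in 25-mg bins
(0–25, 25–50, …; midpoints (lower+upper)/2, first midpoint 12.5) per
day and regresses ln(minutes) on ln(midpoint) by OLS; empty bins are
dropped rather than offset, since ln 0 is undefined and an additive
offset would bias the slope; daily slopes are weighted-week averaged.

## Compositional regression

Compositions are closed to 1440 min.  Zeros (vigorous activity can
legitimately be 0) are replaced multiplicatively: zeros become δ, the
non-zero parts of the row shrink by (total − kδ)/total, and the row is
re-closed; δ defaults to half the smallest positive observed value of
that part.  The "one-for-remaining" analysis expresses the composition
in five pivot ILR bases; with pivot part first and D = 5,

    z_j = sqrt((D−j)/(D−j+1)) · ln( x_(j) / gm(x_(j+1..D)) ),  j = 1..4,

so z1 captures the pivot behaviour relative to the geometric mean of
the remaining four.  Each basis is an orthonormal rotation of the same
log-ratio space, so fitted values, likelihood and the omnibus test are
identical across bases (tested to 1e-8); only the z1 label changes.

The outcome model is a linear mixed model with a school random
intercept (ML), the four ILRs and covariates (sex, age, area
deprivation decile, BMI z-score).  "Accounting for school-level
clustering" is implemented as the random intercept for consistency with
the other mixed models; cluster-robust OLS is available via
`fit(method="cluster")`.  The omnibus association between outcome and
composition is a likelihood-ratio test of the model with versus without
the four ILR terms (χ², 4 df); per-behaviour follow-ups (the z1
coefficient per pivot, with Wald CIs) are flagged for interpretation
only when the omnibus p < 0.05.  Variance inflation factors are
computed on the fixed-effects design across all five bases and reported
as a range.  When the sex coefficient is significant at 0.05 the model
is refitted within each sex.  Mixed fits that land on the zero
cluster-variance boundary (singular Hessian, unusable standard errors)
fall back to OLS with a warning; for the likelihood-ratio test alone
the boundary fit's likelihood is still valid and is used directly.

Single-characteristic associations (sleep quality, rhythm and
acceleration metrics vs outcomes) use the same mixed-model machinery
with one exposure at a time; p-values are invariant to affine rescaling
of the exposure, and BMI z-score is added as a covariate only for the
acceleration metrics.

## Goldilocks search

Per behaviour, candidate ranges are mean ± 3 SD of the observed
compositions on the raw minutes scale, intersected with the observed
min/max, clipped to [0, 1440] and rounded outward to the 10-min grid
step.  SD on raw minutes (not log) is the default because the ranges it
produces are directly interpretable in minutes; the observed-support
intersection is applied afterwards and can be disabled
(`clip_to_observed=False`).  All 5-part lattice points summing exactly
to 1440 are enumerated depth-first with range pruning, in deterministic
lexicographic order (the default grids run to ~10⁴–10⁶ rows; enumeration
is exact, not sampled).  The prediction model for the grid is a plain
fixed-effects linear regression on the ILRs and covariates —
deliberately simpler than the mixed model, as predictions at covariate
reference values (sample means; sex at the sample proportion) do not
involve the school effects.  Grid compositions containing zeros are
routed through the same multiplicative zero replacement before the ILR
transform.  The optimal time-use zone is the most favourable 5% of
predictions (lowest, for difficulty scores); ties at the boundary are
included, so the zone can slightly exceed the nominal fraction.  The
zone is summarised by its closed geometric mean, and a radar-ready
table compares it with the sample's mean composition against guideline
markers (540 min sleep per night; 60 min MVPA per day, MVPA = MPA +
VPA).

## SDQ scoring

The 25 items (0–2) map onto five subscales of five items (emotional,
conduct, hyperactivity, peer, prosocial) using the standard layout with
five reverse-scored items.  Total difficulties (0–40) sums the four
problem subscales; prosocial is excluded as the positive subscale.
Internalising = emotional + peer; externalising = conduct +
hyperactivity.  A subscale with missing items is pro-rated (mean of
present items × 5, rounded) when at least three items are present,
otherwise missing, and pro-rated subscales are recorded per
participant.  Four-band cutoffs (close to average / slightly raised /
high / very high) are shipped as a configurable table with
self-completed-SDQ defaults, not hard-coded truth, as banding
conventions vary by informant and country.  Cronbach's α uses the
standard k/(k−1)·(1 − Σvar(item)/var(sum)) form.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with every planted parameter recorded in a ground-truth table.

* **ENMO**: exp(cosinor + ε) − 1, floored at 0, where the cosinor is
  the anti-logistic model above with per-participant parameters drawn
  from population distributions (minimum 0.3 ± 0.1, amplitude
  4.6 ± 0.2 clipped to [4.25, 5.1], acrophase 14.4 ± 0.8 h, α 0 ± 0.05,
  β 2.0 ± 0.2) and iid Gaussian noise (σ = 0.1) on the log(mg+1) scale
  — the noise lives on the scale the cosinor is fitted on, so the
  fit's error model matches generation.  The amplitude bounds keep
  every participant's daytime plateau above the 48 mg cut-point, so
  between-person light-activity time varies smoothly rather than
  collapsing to zero.  These defaults place cohort mean average
  acceleration in the mid-40s mg, daytime peaks near 70 mg, and the
  five-part composition near (530, 525, 305, 65, 12) min.
* **Sleep**: one planted window per night (onset 22.4 ± 0.5 h clock
  time with ±0.15 h nightly jitter; duration 530 ± 30 min).  Inside the
  window the z-angle is a per-night resting value with 0.3° jitter;
  waking z-angle is high-variability (uniform ±60°).  Awakenings
  (Poisson, mean 10/night; 8 min each; ≥ 31 min apart, ≥ 36 min from
  the window edges) are high-variability, raised-ENMO bouts.  The
  separation keeps every inter-bout rest segment above the detector's
  30-min minimum so planted and detected windows agree; with these
  defaults detected efficiency centres near 87–88%.  Real cohorts show
  more, shorter awakenings (~20/night); the generator trades that for
  exact recoverability at 5-s epoch resolution.
* **Activity bouts**: daily moderate (65 ± 15 min) and vigorous
  (12 ± 5 min) minutes, placed as one block centred on the acrophase
  (vigorous in the middle), with ENMO drawn uniformly inside the
  respective cut-point bands and a multiplicative day-level jitter
  (σ = 0.1) for day-to-day variability — exposed as a parameter since
  within-person variability is rarely reported.
* **Calendar**: the signal runs from noon of the day before the first
  complete day to noon of the day after the last, so all n_days
  calendar days are complete and every night, including the first
  morning and last evening, has a planted window.  The first complete
  day is a Monday, giving 5 weekdays + 2 weekend days by construction.
* **True composition**: the exact daily minutes implied by the planted
  schedule — window duration for sleep, planted bout minutes for
  MPA/VPA, and the noise-free cosinor level classified against the
  cut-points for the ST/LPA split — computed on a 1-min grid; sums to
  1440 by construction.
* **Covariates and outcome**: balanced school assignment; sex (60%
  girls), age group (61.5% children, ages 9.8 ± 0.4 vs 13.1 ± 0.3),
  EIMD decile (discretised normal 6.7 ± 2.9 clipped to 1–10), BMIz
  (0.48 ± 1.22).  SDQ totals come from a linear model on the true
  composition's log-ratios plus covariates, a school random intercept
  (SD 1.0) and residual noise (SD 5.0), rounded and clipped to [0, 40]
  (clipping rate recorded; < 5% under defaults).  The compositional
  effect is specified as a zero-sum gradient on the log scale, chosen
  so the implied first-pivot coefficients are −6.0 for sleep and +4.7
  for sedentary time (the remaining behaviours share the balance
  equally); because the gradient is basis-free, the implied coefficient
  for *every* pivot is known exactly (sqrt(5/4) × gradient entry).
  Higher SDQ = worse mental health throughout.  Item-level responses
  are synthesised by splitting the total multinomially over the four
  problem subscales and each subscale over its items, so item-level
  scoring reproduces the planted totals exactly.

What the generator does **not** emulate: raw 100 Hz signals, device
non-wear and calibration error, naps and irregular schedules,
weekday/weekend behaviour differences, posture changes within sleep,
and realistic item-level SDQ response correlation (α on synthetic items
is a property of the multinomial split, not of a planted latent trait).
Passing tests therefore demonstrate that the estimators recover the
structure they assume, at realistic magnitudes — not that they are
robust to every artefact of field data.

## Validation battery and problem sizes

The self-validation experiments (`move24.evaluation`, run by the test
suite and by `scripts/acceptance.py`) use sizes chosen to finish on one
CPU in a few minutes: cosinor recovery on 200 pure-rhythm participants
× 7 days (median acrophase error ≤ 0.25 h, median amplitude error
≤ 5%); IV on 1000 days of white noise (2.0 ± 0.05); type-I error of the
null omnibus and association tests over 1000 replicates at n = 200
(5% ± 1.5 points); coefficient recovery at n = 300 over five
independent cohorts (the planted value must fall inside the fitted 95%
CI in at least four — per-CI coverage is itself a ~95%-probability
event, verified nominal at 29/30 over 30 cohorts during development);
Goldilocks optimum recovery on a planted interior quadratic (within one
10-min grid step); and cohort calibration at n = 24 (mean average
acceleration within 35–50 mg, mean sleep efficiency 85–90%).

## Known limitations

* The sleep detector is tuned to the generator's clean two-state
  z-angle process; field data with gradual posture drift will need the
  threshold cap and minimum-bout parameters revisited.
* Mixed-model p-values are asymptotic (no small-sample df correction);
  with ~10 clusters the omnibus LRT runs slightly off nominal (measured
  ~4–6% at the 5% level), which the calibration test bounds but does
  not remove.
* The aim-3 prediction model extrapolates linearly in log-ratio space
  across the whole grid; compositions near range corners are far from
  the data and their predictions correspondingly uncertain — the zone's
  compositional mean, not any single grid point, is the supported
  summary.
* VIF among ILR coordinates depends strongly on the cohort's
  composition covariance; the generator's low-dimensional behaviour
  structure yields a wider VIF range than field cohorts typically show.
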