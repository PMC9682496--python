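# Methods

This note documents the models, parameter choices, numerical details and
limitations of `picurisk`. The package's premise: early respiratory
decompensation in PICU patients leaves statistical signatures in
continuous monitoring, charted vitals and labs during the hours before
urgent unplanned intubation, and those signatures can be displayed
(predictiveness heatmaps) and learned (a balanced-bootstrap random
forest) for continuous bedside risk estimation.

## Windows and eligibility

Continuous channels are sampled at 0.5 Hz (a 2-s grid, integer seconds
since hospital admission; intervals are half-open `[start, end)`).
Features are computed in 30-minute windows at a 15-minute stride and
stamped with the window end time, so a feature row summarises the most
recent half hour. A record is *at risk* (eligible) when its timestamp
lies inside a PICU interval and outside every ventilation episode.
Ventilation episodes run from the first to the last ventilator
respiratory-rate measurement in a run, split wherever consecutive
measurements are more than 12 h apart (a gap of exactly 12 h does not
split). Intubations within 15 min of PICU admission or within 1 h after
an extubation are excluded as events; both exclusion intervals are
half-open and measured forward from the trigger.

A window at time t is a case when an (included) unplanned intubation
occurs in (t, t + 12 h]; every eligible window strictly before the event
is kept, including the one ending exactly 12 h before it. Multiple
events in one admission label their windows independently. Under the
4-h sensitivity horizon, records that were cases at 12 h but fall
outside 4 h are dropped from AUC computation rather than relabelled as
controls — they are neither clean cases nor clean controls.

Two event definitions are supported: *chart review* (non-elective,
in-PICU intubations, emulating registry review of indication and
location) and the *computable phenotype* (every recorded intubation).
The first is a subset of the second by construction.

## Monitoring measures

Per window: mean and sample SD (n−1) of HR, RR and SO₂, each missing
when fewer than half of the expected 900 samples are valid; mean
systolic/diastolic pressure using any non-invasive value held or cycled
in the window, invasive pressure only in its absence; lag-zero Pearson
correlations between HR, RR and SO₂ on the shared 2-s grid (≥ 30
pairwise-complete samples, missing for zero-variance channels).

Inter-beat intervals pass a plausibility filter before any cardiac
dynamics measure: intervals outside [250, 2000] ms are removed, then a
sequential rule removes each interval whose ratio to the previous
*retained* interval falls outside [0.6, 1.8]. If fewer than 60 valid
intervals remain, all six cardiac measures are jointly missing. The
filter replaces waveform-level signal-quality assessment — this package
consumes inter-beat series, not raw ECG.

* **sRRI** — sample SD of the valid intervals (ms).
* **COSEn** — −ln(A/B) + ln(2r) − ln(mean RRI), with B and A the counts
  of template pairs of length m = 1 and m = 2 within Chebyshev tolerance
  r = 30 ms (self-matches excluded, both templates drawn from the same
  N − m start indices); natural logarithms, RRI in ms. Missing when
  either count is zero. The tolerance and rate corrections make the
  entropy comparable across heart rates, which is what suits short
  inter-beat series.
* **DFA slope** — first-order detrended fluctuation analysis: integrate
  the mean-centred intervals, partition into ⌊N/n⌋ non-overlapping boxes
  for each integer scale n ∈ {4,…,12}, least-squares-detrend each box,
  and take F²(n) as the mean squared residual; the feature is the
  least-squares slope of ln F² on ln n — twice the conventional DFA
  exponent α. Note the finite-size behaviour at these scales: for white
  noise the exact expectation E[F²(n)] = σ²(n²−4)/(15n) yields a slope
  of 1.216 over scales 4–12, not the asymptotic 1.0; integrated white
  noise gives 3.0. The estimator is left uncorrected (it is a feature,
  not an exponent estimate), and the recovery tests assert the exact
  finite-size values.
* **LDs / LDd** — embed consecutive pairs (RRIᵢ, RRIᵢ₊₁) and count each
  point's neighbours within Chebyshev r = 30 ms (self excluded). LDd is
  the fraction of points matching *no* other point; LDs the fraction
  matching very many (more than 20 % of all points). The original
  construction is published only by citation; this concrete
  neighbour-count definition implements the verbal description and is
  fixed and oracle-tested.
* **AF probability** — a declared surrogate,
  logistic(COSEn + 5·(sRRI/mean RRI) − 1): erratic, high-entropy,
  high-variability rhythms score high. The interface is stable so a
  published atrial-fibrillation classifier can be substituted.

The template-counting measures (COSEn, LDs/LDd) use at most the most
recent 400 filtered intervals per window, keeping the O(n²) counts
tractable at pipeline scale; the oracle-equivalence tests run on series
of ≤ 100 intervals where the cap never binds.

The enumerated monitoring set has 17 members (p = 39 with the 8 vital
features, 13 lab features and age); the feature-matrix schema accepts an
additional configured monitoring column (p = 40) without changing
mtry = ⌊√p⌋ = 6.

## Clinical features

Flowsheet vitals and labs are carried onto the window grid by
sample-and-hold: the last measurement at or before the query time is
used, and a value whose staleness strictly exceeds its horizon — 24 h
for flowsheet vitals, 48 h for labs — is censored (staleness exactly at
the horizon is kept). Derived quantities are computed *after* holding:

* **FiO₂** — a charted value wins; otherwise 0.21 + 0.03 per L/min of
  supplemental oxygen flow, capped at 1.0. The linear flow rule and its
  0.03/L coefficient are package defaults exposed in the API, not
  literature constants.
* **ePFR** — estimated PO₂/FiO₂: SpO₂ is capped at 0.96 (the
  dissociation curve is nearly flat above), PO₂ is the unique positive
  root of S = (23400·(P³ + 150P)⁻¹ + 1)⁻¹ solved by bracketed bisection
  to |ΔP| < 0.01 mmHg, and the ratio is PO₂/FiO₂.
* **Anion gap** = Na − Cl − HCO₃; **BUN/Cr** = BUN/creatinine (missing
  when creatinine is 0). Each derived value is missing when any
  component is missing or stale.

Age is the age at hospital admission in fractional years, constant per
admission. Temperature is carried in °C.

## Risk model

`UnplannedIntubationForest` fits 800 classification trees; each tree's
training sample is a bootstrap of the case rows plus an equal-sized
with-replacement sample of control rows (per-tree balanced bootstrap —
the standard forest idiom; a single global rebalance is the obvious
alternative and the construction is isolated in `fit()` if one wants to
swap it). Six features (⌊√p⌋) are candidate splitters at each node; a
tree classifies a record by its leaf's majority class, and the model
output is the vote fraction v ∈ [0, 1] at resolution 1/800.

Scaling: relative risk = v / v̄ where v̄ is the mean vote over the
training (reference) population — eligible records only, the same
population over which AUC is computed; predicted probability =
relative risk × π₁₂ₕ, clipped to [0, 1], where π₁₂ₕ defaults to the
training fraction of case records and can be overridden (0.0063 is the
source cohort's published 12-h prior, used in worked examples). Mean
relative risk over the reference set is exactly 1.

Missing predictors are imputed with age-decile medians: decile edges of
age and per-decile medians are fitted on training data and reused for
test rows; an empty decile falls back to the training global median; a
feature with no observed training values raises. Observed values are
never altered.

Marginal risk profiles vary one feature across its observed range with
all other features at their training medians and report
ln(p/(1−p)) of the predicted probability. The random-feature screen
appends an i.i.d. uniform column, refits, and reports permutation
importance (mean drop in training AUC over shuffles) relative to the
random column's.

## Evaluation

Folds are assigned to whole admissions (5 folds of near-equal admission
count), so no patient's records ever appear in both training and test —
row-wise folds would leak repeated measures. Imputation and scaling
constants are refitted inside each training split. AUC is the
Mann–Whitney probability that a random case record outscores a random
control record (ties ½), computed over all at-risk records; per
patient-type AUCs subset the same out-of-fold predictions. Confidence
intervals resample admissions with replacement (200 replicates,
percentile 2.5/97.5; single-class replicates are redrawn). The
above-chance reduction between two models is
100 × (AUC_ref − AUC_alt)/(AUC_ref − 0.5).

Time-to-event curves bin each event's out-of-fold relative risks by
time before the event (15-min bins, 24-h span, matching the window
stride) and average across events. Each bin is compared with the same
events' risk 8 h earlier by a one-sided paired Wilcoxon signed-rank
test (the comparison is within patients, so the paired test is used
even where a rank-sum test might be named); a bin is flagged at
p < 0.05 and the test is withheld below 6 pairs.

The cohort summary reports median (IQR) with Wilcoxon rank-sum tests
for numeric rows and percentages with two-proportion z-tests for
binary rows, by event status.

## Predictiveness heatmaps

One replicate samples 8 measurements (without replacement when
possible) from the 12 h before each event and 8 from each admission
without an event — or far from its events: outside every 12-h pre-event
window (all sampled windows are already eligible, hence outside
ventilation). Decile edges for the feature and for age are the
replicate's pooled sample percentiles and are shared across patient-type
panels, so panels are directly comparable. A tile at (feature decile i,
age decile j) is P(case | feature ∈ bandᵢ, age ∈ bandⱼ)/P(case), where
bandᵢ is the 20-percentile-wide quintile centred on decile i's midpoint
(truncated at the range ends; band bounds are interpolated between the
stored decile edges). Tiles with fewer than 20 samples are missing
rather than noisy. Thirty replicates are averaged tile-wise; the
marginal risk profile is the occupancy-weighted average over age deciles
and panels.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not physiology. Admissions draw a patient type
(medical/cardiac/non-cardiac ≈ 45/24/31 %), an age (cardiac surgery
heavily skewed to infancy; others a mix of an infant mode and a uniform
spread to 18 y), a monitored stay (uniform 20–32 h), and an event with
configurable probability (default 0.033, near the source cohort's rate;
an optional multiplier raises risk below an age threshold for
signature-recovery experiments). Baseline vitals are piecewise-constant
pediatric norms by age band with AR(1) noise (e.g. HR marginal SD
6 bpm); inter-beat intervals come from time-rescaling the HR trend to
unit cumulative intensity plus AR(1) interval noise (SD 25 ms), with
rare implausible artifacts (rate 2×10⁻⁴) to exercise the filter.

The prodrome is a linear ramp over the final 12 h before the event with
per-type effect sizes; defaults ΔHR +25 bpm, ΔRR +10 /min, ΔSpO₂ −0.05,
ΔSBP −15 mmHg, O₂ flow +4 L/min, HCO₃ −5, WBC +6, Plt −60, and
inter-beat noise shrinking to 0.5× — all ≥ 2 baseline SDs at the event
for the vital-sign channels. Flowsheet charting is deliberately
imperfect, as real charting is: q2h cadence, single-observation noise
(SD 2) with integer rounding for HR/RR, SpO₂ to 0.01, flow to the half
litre, and 25 % of admissions on baseline supplemental oxygen. This is
what leaves genuine added value in the continuous channels (precision
of 30-min means, SD/correlation/variability features) over the charted
ones. Elective operating-room intubations (with OR records consistent
with patient type) are generated for a configurable fraction of
surgical admissions so the chart-review/computable-phenotype contrast
is exercisable. Mortality, length of stay and sex are drawn with
event-dependent rates for the cohort summary table.

What passing recovery tests show: the pipeline detects the planted
ramp structure out of fold (AUC > 0.85 at n = 400), orders horizons
correctly (4 h ≥ 12 h), finds monitoring features additive, and
reproduces an injected young/low-RR hazard as a hot heatmap corner.
What they do not show: performance on real PICU data — real prodromes
are heterogeneous, nonlinear and confounded by treatment; artifacts are
structured, charting is adaptive (sicker patients are charted more
often), and event times carry decision delays. The published cohort
AUCs (0.696 at 12 h, 0.766 at 4 h) are properties of institutional data
this package cannot access and are treated only as directional
references, never as assertable numbers.

## Problem sizes and determinism

Recovery experiments use 400-admission cohorts with 20–32 h monitored
stays (≈ 38 000 eligible windows) — large enough for stable record-level
AUCs and occupied heatmap tiles at desk scale. All randomness flows
from explicit integer seeds (config seed, fold seed, forest seed);
identical seeds give byte-identical cohorts, fits and metrics. The
acceptance script derives independent sub-seeds from its single `--seed`
via `numpy.random.SeedSequence`.

## Known limitations

* The AF probability is a surrogate, not the published classifier; its
  coefficients are package defaults.
* The FiO₂-from-flow rule ignores delivery device and minute
  ventilation.
* The RRI plausibility filter stands in for waveform signal-quality
  analysis; it cannot detect in-band artifact.
* LDs/LDd follow this package's explicit neighbour-count definition of
  a construction published only by citation.
* Sample-and-hold carries no uncertainty: a 47-h-old lab counts the
  same as a fresh one until censored.
* The generator's single-interval PICU stays and single-event-per-
  admission default understate the clustering of real re-intubations
  (the labeling and evaluation code handle multiple events; the
  generator produces them only via configuration).
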