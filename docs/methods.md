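# Methods

`chronomeal` re-implements, as a tested pipeline, a chrononutrition
analysis design used in cross-sectional studies of young adults: weekly
meal-timing exposures referenced to the sleep/wake cycle are derived
from 24-h dietary recalls and actigraphy summaries, combined with a
fasting cardiometabolic panel, and related to outcomes by sex-stratified
standardized-beta linear regression with multiplicity control.  Because
participant-level data of such studies are not public, the package
ships a first-class synthetic cohort generator with planted effects, and
all claims about the pipeline are established on that generator.

## Study design being emulated

Each participant contributes

* three non-consecutive 24-h dietary recalls (two working days, one
  non-working day), each a list of timed eating events with energy;
* seven consecutive actigraphy nights (five working, two non-working)
  with sleep onset, offset and daily wear time (sleep detection itself
  is upstream and out of scope);
* one fasting visit: anthropometry, three-visit blood pressure,
  glucose, insulin, lipids, plus pre-computed covariates (a priori
  Mediterranean-diet pattern score, light physical-activity minutes).

## Time axes

Averaging clock times across midnight is done on linear axes:

* sleep variables live on a **noon-anchored axis** [12, 36): 01:13
  becomes 25.217;
* eating events live on a **within-day axis**: an event before the
  rollover hour (04:00 by default) belongs to the previous recall day
  and maps to hour + 24.

Results are reduced mod 24 only for reporting.  All weekly means are
weighted 5/7 (working) and 2/7 (non-working); the weights are
configurable since the original "weighted mean" is otherwise
unspecified.

## Derived variables

* **Nightly midsleep** = onset + duration/2; **weekly midsleep** is the
  weighted mean of the stratum means; **social jetlag** = non-working
  minus working midsleep (kept signed; an absolute column is emitted
  because descriptive tables usually print magnitudes).
* **Actigraphy validity**: a participant is excluded when more than 4
  days register under 16 h of wear or no weekend day is present.
* **Dual-entry reconciliation**: recalls entered independently by two
  coders are compared on daily total energy with the percent CV
  (sample SD, n−1).  CV ≤ 5% → event-wise mean of the two entries;
  otherwise a third entry is required and the pair with the lowest CV
  is averaged, ties preferring the re-entered dataset.  The CV target
  quantity (daily energy) is this package's documented contract; the
  original protocol does not state it.
* **Eating window** = last − first caloric intake per day; **caloric
  midpoint** = earliest event at which cumulative energy reaches ≥ 50%
  of the daily total; **eating midpoint** = temporal midpoint of the
  eating window.  The eating-jetlag construct of the chronobiology
  literature uses the temporal midpoint; both midpoints are emitted so
  either reading can be reproduced.
* **Midsleep-anchored intervals**: time from midsleep to first intake
  and from last intake to midsleep, computed from *weekly means* of
  each ingredient (recall days and actigraphy nights do not overlap by
  design, so day-matched pairing is impossible), reduced mod 24 into
  (0, 24).  For a single day referenced to a single midsleep the
  identity `msp_to_first + eating_window + last_to_msp = 24` is exact
  provided both intakes fall within 24 h of the midsleep point; on
  weekly means it holds to within rounding (cohort means come out at
  24.00 ± a few hundredths).
* **Breakfast status**: consumer iff every one of the three recall days
  has a caloric event of ≥ 50 kcal no later than 11:00 on the
  within-day axis (so a 00:30 snack never counts); a "breakfast" label
  overrides the time rule.  Cutoff and threshold are configurable
  conventions — the emulated protocol never defines "breakfast".
* **Markers**: BMI; lean-mass index; mean BP = DBP + (SBP − DBP)/3 on
  the three-visit averages; HOMA-IR = glucose × insulin / 405;
  Friedewald LDL (missing and QC-flagged at TG ≥ 400 mg/dl).
* **Risk Z-score**: within each sex, waist, mean BP (configurable to
  SBP), glucose, HDL (sign-flipped) and triglycerides are standardized
  with the sample SD and averaged.  Complete cases only; no prorating.
  The stratum mean is 0 by construction, but the mean of five
  imperfectly correlated Z-scores has SD < 1; an optional
  re-standardization switch (off by default) restores unit SD, and no
  SD = 1 claim is asserted anywhere.

## Statistical layer

Triglycerides, total cholesterol, HDL-C, LDL-C and HOMA-IR are
log10-transformed before analysis; mean BP and the risk score are not.
Simple OLS reports the standardized slope (= Pearson r), adjusted R²
and the two-sided slope p.  Adjusted models add the confounder set
{sex (pooled stratum only), Mediterranean-diet pattern, light PA,
midsleep point or sleep duration, BMI}; sleep duration substitutes for
the midsleep point when the exposure is itself midsleep-anchored, and
BMI is dropped when BMI is the outcome.  Group contrasts use Welch's t
(breakfast groups) and one-way ANOVA (sex comparison; with two groups
F = pooled t²).  Multiplicity is controlled per table and stratum —
the family definition is a documented choice — by Benjamini–Hochberg
FDR (default, matching the footnotes of published result tables) or the
Hochberg step-up FWER procedure.  Note that neither step-up procedure
is idempotent on its own output; the asserted invariants are
monotonicity, p_adj ≥ p and capping at 1.

## Synthetic cohort generator

The generator is latent-anchor based.  Each participant draws weekly
latents — midsleep point N(05:04, 1.08 h), sleep duration N(7.85,
1.2 h), social jetlag N(1.42, 1.15 h), midsleep-to-first-intake gap
N(4.87, 1.40 h), eating window N(12.0, 1.7 h) men / N(12.2, 1.4 h)
women, eating jetlag N(1.2, 1.1 h) — and biomarker marginals per sex
(means/SDs from the descriptive statistics of the emulated cohort;
skewed variables parameterized log10-normally with SD ≈ IQR/1.349).
Nights and recall days realize the anchors with Gaussian jitter
(defaults 0.35 h nightly midsleep, 0.5 h nightly duration, 0.3 h meal
times) constructed so that the 5/7–2/7 weighted weekly means are
unbiased for the latents.  Within-person day-to-day variance is not
reported by observational studies of this design; these defaults are
free parameters chosen once as plausible, and are not claimed to match
any real sample.  The printed sleep onset (01:13) and duration (7.85 h)
of the emulated cohort imply a midsleep of 05:09 while its midsleep row
prints 05:04 (medians and means mix in such tables); the generator
anchors on the midsleep value and derives onset.

In men, log10 HOMA-IR is generated as
`μ + s·(β₁·z(window) + β₂·z(gap) + σ·ε)` with planted standardized
slopes β₁ = −0.605 and β₂ = +0.485 and σ² = 1 − β₁² − β₂², so that the
marginal SD is the configured `s` and a simple-OLS refit recovers the
planted slopes in expectation (window and gap are generated
independently).  In women both slopes are zero.  Insulin is back-derived
from HOMA-IR and glucose, keeping the panel internally consistent.
Breakfast skipping deletes the first event of one random recall day
with participant-level probability 0.10 (a modest skipper share;
time-rule misses add further classified skippers).  Dual entries
rescale a day's energies so the A-vs-B CV follows |N(0, 2.5%)|; days
exceeding 5% receive a near-exact third entry.

**What passing tests show — and what they do not.**  The generator
produces independent biomarkers (no waist–BMI–BP correlation
structure), symmetric jitter, exactly 3 + 7 observation counts and no
missingness outside the planted mechanisms.  Tests on it validate the
arithmetic, the filtering contracts and the recoverability of planted
effects through the full pipeline; they cannot validate robustness to
the correlated measurement error, informative missingness or recall
bias of real dietary data.

**Attenuation.**  Refitted slopes are mildly biased toward zero
relative to the planted latents because the measured weekly exposures
carry day-level noise (jitter plus breakfast-skip deletions): at 2000
men per seed over 20 seeds the refit means are ≈ −0.59 (planted
−0.605) and ≈ +0.45 (planted +0.485).  This is ordinary regression
dilution, quantified by `analysis/05_parameter_recovery.py`, and is
well inside the ±0.05 recovery band asserted in the tests.

## Numerical choices and degenerate inputs

Sample (n−1) SDs throughout.  Zero-variance regressors, single-group
ANOVAs, sub-2 groups, inverted BP readings, nonpositive glucose and
out-of-range clock strings raise typed errors; nonpositive values of
log-transformed outcomes, missing day-type strata and TG ≥ 400 LDLs
become missing values with QC flags.  Normality for the descriptive
table is decided by Shapiro–Wilk at α = 0.05 per stratum (the emulated
protocol lists several checks without a decision rule).  Monte-Carlo
problem sizes (500-participant cohorts for descriptive checks, 20
seeds × 2000 per sex for recovery, 1000 replicates for type-I
calibration) were chosen as the smallest sizes at which the quantities
stabilize well inside their tolerance bands.

## Known limitations

Real EvalFINUT-style nutrient coding, food items, DXA processing,
accelerometer signal processing, activity-intensity classification and
diet-quality indices are out of scope; covariates enter as plain
columns.  The multiplicity family in the original analyses (per table?
per stratum? pooled?) is unknown; per-table-per-stratum is this
package's documented default.  Whether the original eating midpoint was
temporal or caloric is unknown; both are emitted.
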