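# Methods

This note documents the models implemented in `surgecast`, the choices made
where the design was genuinely open, the synthetic data the package is
validated on, and what that validation does and does not establish.

## The rolling-window forecaster

For a day of interest (DOI) `d`, the observation-collection step gathers
historic counts in calendar-matched positions:

* **current year:** the θ same-weekday dates strictly before `d`
  (offsets −7, −14, …, −7θ days);
* **each lag year k = 1..τ:** the 2θ+1 same-weekday dates centred on the
  *corresponding day* of `d` in that year.

The prediction step aggregates the pooled counts; the default is the uniform
(unweighted) arithmetic mean. Median, min, max and a mean-of-yearly-means
variant are available. With complete coverage the collection holds exactly
θ + τ(2θ+1) counts; shorter histories skip unavailable dates and report a
coverage fraction instead of failing, so a 1-year configuration runs on a
1-year series.

**Corresponding day.** "Same day-of-week and week-of-year, one year earlier"
admits two readings, both implemented:

* `WEEKDAY_364` (default): subtract 364 days (52 whole weeks) per lag year.
  Weekday is preserved exactly; month/day drift by 1–2 days per year, which
  is the behaviour described for the method this implements.
* `ISO_WEEK`: same ISO week number and ISO weekday, ISO year reduced. When
  the DOI sits in week 53 and the target year has 52 weeks, week 52 is used
  (nearest existing week, deterministic). Feb-29 needs no special-casing in
  either mode because all offsets are in days/weeks.

**Current-year window.** Whether the within-year window uses same-weekday
dates only or all days of the preceding θ weeks is not fixed by the method's
published description; same-weekday-only is implemented, because mixing
weekdays into a pooled mean would blend systematically different levels
(weekday ~85 vs weekend ~22 counts) and because it makes the collection rule
uniform across years.

**Holidays.** The default (`CALENDAR_ONLY`) collection is purely date-offset
based: a holiday DOI is predicted mostly from non-holiday history and will be
over-predicted, which matches the known failure of this model family on
unprecedented holiday clusters. `HOLIDAY_AWARE` mode instead predicts a
holiday DOI from historic holidays and weekend days (augmenting with all
holidays in the τ-year lookback when fewer than 3 matched dates survive) and
drops holiday source dates for non-holiday DOIs. Holiday calendars are always
explicit input files, never computed from a locale library, for
reproducibility across regions.

**Prediction intervals.** The interval construction is an implementation
default, not intrinsic to the method: `point ± t_{(1+level)/2, n−1} · s ·
√(1 + 1/n)` with `s` the sample standard deviation of the collected counts,
clipped below at 0; singleton or zero-variance collections give a degenerate
interval. On the stationary Poisson scenario this achieves ~93–96% empirical
coverage at the 95% level (the acceptance script measures it each run). It is
approximate — counts are Poisson, not normal, and collected counts are not
identically distributed when seasonality or trend is present.

**Rounding.** Point forecasts are integers (round half away from zero) in
CLI output and in benchmark evaluation of the rolling window, matching how
such predictions are reported operationally; regression forecasts are
evaluated unrounded. Both conventions are overridable.

## Calendar-feature regression

Features per day: relative day index `t` (whole days since the training
origin), an eight-way one-hot day type (Mon..Sun + public holiday; a holiday
overrides its weekday — "an additional type of day", not a separate flag),
and first-order Fourier terms `sin(2πt/m)`, `cos(2πt/m)` with `m = 365` days.
Only the first harmonic is used. The eight indicators sum to one, so design
matrices carry no separate intercept (linear models are fitted without one;
the GLMs use the indicators as their intercept block, keeping all eight
coefficients identified).

Estimator families are adapters over scikit-learn (linear, tree, random
forest, SVR with linear/RBF/sigmoid/poly kernels, bagging, gradient
boosting), statsmodels GLM (Poisson, negative binomial with fixed dispersion
`alpha`, default 1.0), and optionally xgboost (reported unavailable rather
than failing when not installed). Arbitrary hyperparameter maps pass straight
through; no tuner is built, because the scheme under study is the feature
encoding and comparison protocol, not estimator tuning. Stochastic families
take a seed (default 1); identical seed and data give identical predictions.
Negative predictions are clipped to 0 before evaluation, since the target is
a count. Each stream (emergency / elective / overall / specialty) is fitted
separately.

The ensemble is a uniform-weight vote — the unweighted mean — of Random
Forest, Bagging and Gradient Boosting, hence permutation-invariant and
bounded by its bases.

## Evaluation protocol

Daily theatre arrivals are time-dependent, so validation is chronological
only: training is the 1, 2 or 3 whole years ending the day before the test
start; testing is the following year. The whole horizon is forecast in one
pass; nothing fitted or collected may touch test-period counts (an
instrumented test asserts this for every model family).

Metrics: MAE, MSE, RMSE, and the headline MAPE built from
`PE_t = (Y_t − F_t)/Y_t × 100` — negative PE means over-estimation. MAPE is
undefined at `Y_t = 0`, hence masks: emergency/overall evaluations keep all
days (residual zero-count days are dropped with a warning); elective drops
weekends and public holidays (no electives are scheduled then); specialty
additionally drops the specialty's zero days. Breakdowns report per-group
MAPE with interquartile spread by day-of-week (holiday days grouped under
their weekday) and by month.

Model comparison: paired two-tailed t-tests on per-day absolute PE aligned by
date — paired because all models are scored on the same masked days. The
Bonferroni threshold is α/K with K the number of comparisons actually
executed in the run, reported in the output (K is not fixed a priori because
the roster is user-configurable).

## Synthetic data: what it emulates and what it does not

The generator's rate is `baseline · daytype_mult · exp(amp·cos(2π(t −
phase)/365)) · exp(trend·t/365) · shock_mult`. Defaults are back-solved from
the published descriptive statistics of a 783-bed metropolitan hospital's
four-year extract: grand mean ≈ 68.3 surgeries/day, Friday noticeably higher
than other weekdays, weekends ≈ 21–22, holidays weekend-like, monthly means
ranging roughly 61–71. Two reconciliations were needed:

* The published day-of-week means (weekdays 79–84, Friday 93, weekend 21)
  imply a grand mean near 66, below the published overall volume (≈ 68.3/day).
  The defaults keep the relativities (Fri ≈ 95 including holiday Fridays,
  weekend ≈ 22) and sit Mon–Thu at 84–87 so the grand mean lands near 67.
* The published monthly profile (low Jan/Apr/Dec, high Nov *and* May) is not
  a single annual cosine; it is largely a holiday effect. The generator keeps
  one annual cosine (amplitude 0.06, peak ~1 Nov) plus holiday dips, so its
  May is mid-range rather than high.

Overall counts are Poisson by default (negative-binomial dispersion is off —
no overdispersion estimate is published for the target data); elective counts
are a binomial thinning with share 0.65 on working days and 0 on weekends and
holidays; specialties are a multinomial split with day-of-week-modulated
weights for the ten most frequent codes. The synthetic holiday calendar is
Australian-style: eight fixed or rule-based dates plus computed Easter
(Good Friday, Easter Monday), ~10 per year.

Scenarios: `WEEKDAY_ONLY` (noiseless, weekday-determined — the exactness
fixture), `CALIBRATED_DEFAULT` (the study conditions), `PANDEMIC_SHOCK`
(April 2020 at 30% of normal demand, emulating a lockdown month),
`SPECIALTY_SPLIT` (specialty streams written out).

**What passing tests show — and don't.** On synthetic data the rolling
window's year-ahead MAPE sits ~1% (relative) above the true-mean oracle,
i.e. the method extracts essentially all the signal the generator contains.
Real hospital data contain structure the generator deliberately omits:
surgeon timetabling and elective booking policy (the dominant source of
elective unpredictability), holiday *clusters* and bridge days, school terms,
weather/epidemic effects, and serial correlation beyond the calendar. MAPE
values on synthetic data therefore characterise the estimator, not expected
real-world accuracy; on the real extract this method family reports ~9.5–13%
MAPE depending on stream, which desk-scale simulation cannot and does not
reproduce.

## Numerical and engineering choices

* Dates are proleptic-Gregorian `datetime.date`; day differences are exact.
* Missing dates in demand CSVs are zero-filled with a warning (hospital
  extracts omit zero-activity days); negative/non-integer counts and
  duplicate (date, stream) rows are hard errors naming the row.
* Splits use calendar years (`test_start − n` years), so leap years are
  handled by the calendar, not by 365-day arithmetic.
* Rounding of point forecasts is half-away-from-zero, applied after
  aggregation; interval bounds are clamped to bracket the (possibly rounded)
  point.
* Problem sizes in the test-suite and acceptance script are the study design
  itself — 3-year history, 365-day horizon — since the method is cheap
  (a full year forecasts in well under a second).
* Seeds: the generator and every stochastic estimator default to seed 1; the
  acceptance script derives all randomness from its `--seed` argument.

## Known limitations

* The prediction interval is a heuristic default (see above); calibrated
  intervals for counts (e.g. Poisson predictive intervals) are future work.
* `HOLIDAY_AWARE` augmentation pools holidays across seasons, which can bias
  holiday forecasts when seasonality is strong.
* The ISO_WEEK correspondence is exposed but less tested against real
  calendars than the 364-day default.
* No within-horizon updating: a deployed system would refresh forecasts as
  new observations arrive; here the one-pass year-ahead protocol is kept
  because that is the evaluation design under study.
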