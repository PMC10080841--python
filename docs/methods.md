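# Methods

`stackcast` forecasts a daily hospital-admission count from its own recent
history, short-term environmental exposure, and the calendar.  This note
records the model, the synthetic data it is validated on, and the numerical
and design choices a maintainer would want to know.

## The forecasting model

### Design matrix

For prediction day *t* the predictors are:

* **Admission lags** — `HAs Lag x` for x = 1..L plus the moving mean and
  sample SD (ddof = 1) over the window, L = 6 by default (the conventional
  short-term exposure window in environmental epidemiology).
* **Environmental lags** — the same eight columns for each of the ten series
  PM2.5, PM10, PMc, SO2, NO2, CO, O3, AQI, TEM, RH (88 lag columns total
  with the target series).
* **Calendar features** — day of week, month, meteorological season
  (Mar–May = spring … Dec–Feb = winter), year ordinal, serial timestamp, and
  binary holiday/workday/first-workday/last-workday flags.  First/last
  workday are defined relative to contiguous workday runs, so a holiday
  midweek creates new run boundaries.

DOW, MON, SEA and YEAR are one-hot expanded with the category set frozen on
the training block (full encoding, no dropped level; a test-only category —
the test year — becomes an all-zero indicator with a logged warning).
Continuous columns are min–max scaled with training-block minima/maxima and
no clipping, so test values may fall outside [0, 1]; binary indicators are
left untouched (scaling would be a no-op).  The target stays on the raw
count scale so errors are in admissions per day.  Missing environmental
cells are linearly interpolated in time (edge runs extended with the nearest
value); counts are never imputed.  The first L rows are dropped rather than
padded with fabricated history.

The split is chronological (train on the first three years, test on the
fourth).  Lag features are computed on the full panel before splitting, so
test rows keep their true history; no training-fitted statistic sees a test
row.

### Two-phase stacking

Phase one fits four heterogeneous base learners — ridge regression, random
forest, gradient-boosted trees, and a one-hidden-layer feedforward network —
under chronological 5-fold cross-validation: the training block is cut into
five contiguous, time-ordered folds (earlier folds take the remainder rows);
for each fold *i*, learner *j* is trained on the other four folds and
predicts fold *i* and the test rows.  That is 20 fits, each logged with
learner, fold and training-row count.  The out-of-fold predictions,
concatenated over folds, form one meta feature per learner for the training
rows; on test rows the five fold models are averaged.  Training a fold model
on folds *after* its own fold is deliberate (it mirrors the stated
cross-validation protocol); a `forward_chaining` flag restricts fitting to
earlier folds for users who prefer strict causality, at the cost of a
degenerate first fold (filled with the training-mean prediction).

Phase two fits an elastic net (squared error + combined L1/L2 penalty) on
the four meta features plus the *key features* — by default every calendar
and admission-lag column — so the combiner can condition its mixture on
where in the week/season/trend a day falls.  With both penalties zero the
fit dispatches to exact least squares, since coordinate descent is undefined
at alpha = 0.  Predictions are real-valued and never rounded; all metrics
are computed on the continuous scale.

### Hyperparameter tuning

Grid search fits each candidate on the chronologically first 80% of the
relevant training design and scores MAE on the last 20%; ties go to the
earlier grid point.  The winning combination is then used in the
cross-validation fits (no refit inside the tuner).  The default grids are
small and conventional (ridge penalty, tree leaf size/depth, network L2,
elastic-net alpha and l1_ratio); all are configurable.  The network default
is one hidden layer of 128 rectified-linear units, batch 64, L2 1e-2,
early stopping on 10% of its fit rows with patience 25 — chosen because
smaller/default-configured networks were unstable on ~900-row fold fits and
contributed a useless meta feature.

### LDS re-weighting

Daily counts are imbalanced: holiday troughs and winter peaks are rare.
Within each calendar year (the counts trend upward, so a count that is
ordinary in one year is rare in another), the training labels are binned at
width 1 count, the histogram is convolved with a symmetric kernel (default
Gaussian, 5 bins wide, sigma 2 bins; delta reduces exactly to classical
inverse-frequency weighting), and each row is weighted by the inverse of the
smoothed density at its label.  The kernel is truncated at the label-range
boundary without renormalization.  Weights can be clipped at a configurable
maximum (off by default) and are rescaled **globally** to mean one — global
rather than per-stratum, so a year whose labels are rarer overall genuinely
up-weights against the other years.  The weights enter the elastic-net loss;
scikit-learn's sample-weight handling satisfies the duplicate-row ==
doubled-weight identity to machine precision, which the tests assert.

### Evaluation

MAE, RMSE, MAPE (reported as a fraction: 0.145 = 14.5%) and R².  MAPE
requires positive observations unless an epsilon guard is configured.
Model comparisons use a **paired** two-sided t-test on per-day loss vectors
(absolute errors for MAE, squared for RMSE, absolute-percentage for MAPE),
pairing on the shared test days; a zero-variance nonzero difference reports
p = 0 with a warning.  Relative improvements are percent changes against the
per-metric best individual model.  No multiple-testing correction is
applied.

### Explanation

Attributions are permutation-estimated Shapley values computed on the
**original** design columns through the full two-phase pipeline, so they
live on interpretable inputs (temperature lags, pollutant lags, calendar
indicators), not on meta features.  For each explained row and each of a
small number of random feature orderings (default 4–6; half are used
reversed as antithetic pairs), every background row (default: a seed-fixed
100-row subsample of the training design; the benchmark uses 60) is morphed
feature-by-feature into the explained row and the mean prediction increment
at each step is credited to the feature introduced there.  By construction
the base value (mean background prediction) plus all attributions equals the
model prediction exactly — additivity is asserted at build time with
relative tolerance 1e-6 — and for an additive model the estimate equals
coefficient × (value − background mean) for any single ordering.

Per-column values are summed per underlying variable (all eight TEM-derived
columns into `TEM`; one-hot members into their source), preserving
additivity, then rolled up into three parts: base value, a *regular*
difference from calendar + admission-history variables, and a *volatile*
difference from environmental variables.  The accounting of the
environmental contribution compares the metrics of the partial prediction
(base + regular) with the full prediction.  Local waterfalls start from the
regular baseline and list environmental variables by decreasing
|attribution|; dependence exports are raw (feature value, attribution)
pairs with no smoothing.

## The synthetic panel generator

Real admission registries of this kind are access-restricted, so validation
uses a generator whose ground truth is known.  The count intensity is
log-linear:

    log mu(t) = log(baseline) + trend * years(t)
                + A * cos(2*pi*(doy - peak)/365.25)
                + weekly(dow) + holiday * 1{holiday}
                + sum_P sum_{x=1..6} c[P][x] * z_P(t - x)

with counts drawn negative-binomially (gamma–Poisson, dispersion theta) and
environmental series built as seasonal harmonics plus lag-1 autocorrelated
noise on the scales of urban monitoring data.  PM10 = PM2.5 + PMc by
construction, and the air-quality index is a documented monotone proxy
(100 × the worst pollutant/reference ratio, references near the Chinese
level-2 breakpoints) — a composite index is only defined up to its
sub-indices, and a deterministic monotone stand-in suffices for method
testing.  The holiday calendar is synthetic: Jan 1–3, Oct 1–7, plus a
movable 7-day February block per year emulating a lunar-festival week.

Default calibration (baseline 51.5, trend 0.14/yr, annual amplitude 0.55,
weekday/weekend effects up to −0.28 log on Sundays, holiday −0.70 log,
theta 45) reproduces the marginal shape of a large-city cerebrovascular
admissions series: mean ≈ 69, SD ≈ 28, minimum ≈ 10 (holiday weeks), maximum
≈ 200 (polluted winter days), quartiles ≈ 51/66/85.  The structure/noise
split matters as much as the marginal moments: dispersion 45 leaves roughly
a quarter of the count variance irreducible, matching the predictability a
well-fit model achieves on real data of this kind (R² in the 0.6–0.8 range),
whereas a heavily overdispersed calibration with the same marginal SD would
bury the differences between learners in white noise.  The environmental
effects encode the documented epidemiology — positive short-term effects of
heat, ozone, and particulate/gaseous pollution, a weak protective humidity
effect — with the temperature effect (Σc = 0.28 per SD over lags 1–6) made
strong enough, and temperature's seasonal amplitude moderate enough, that
the *conditional* heat effect is identifiable rather than swamped by
temperature's role as a season proxy.

What the generator deliberately does **not** emulate: station-level spatial
structure, hourly-to-daily aggregation, regulatory AQI arithmetic, reporting
artifacts, or exposure–response nonlinearity.  Passing tests therefore show
that the pipeline recovers known structure of this kind, not that it would
achieve any particular accuracy on a specific real registry.

## Benchmark problem sizes

The stochastic acceptance properties run the full protocol (tuned base and
meta learners, LDS, reduced ensemble sizes: 100 trees, 100 boosting rounds,
500 network iterations) on ten generator seeds of the default 1461-day
panel.  The explanation benchmark explains 60 test days spread evenly over
the test year against a 60-row background with 4 permutations.  These sizes
keep a full validation run to a few minutes per seed on one CPU while
leaving the measured properties stable across independent seed sets.

## Known limitations

* The stacked model's edge over the best single learner is small (a few
  percent) whenever base-learner residuals are highly correlated; the
  dominance property is a statement about typical seeds, not every seed.
* LDS trades a little bulk accuracy for large error reductions on rare
  high/low-count days; on some seeds its overall MAE is slightly worse than
  the unweighted stack.
* The permutation explainer's cost grows as features × background ×
  permutations × samples; defaults are sized for the ~120-column design.
* Test-year categories unseen in training (the year indicator) encode as
  all zeros; the trend must be carried by the timestamp and lag features.
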