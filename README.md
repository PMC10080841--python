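# stackcast

Stacked-ensemble forecasting of daily hospital admissions from lagged
admissions, air-quality, meteorological and calendar features — with
label-distribution-smoothing (LDS) re-weighting for imbalanced counts and
permutation-Shapley explanation of the fitted ensemble.

## Who this is for

Health-services and environmental-epidemiology groups forecasting short-term
demand (e.g., daily cerebrovascular admissions) from restricted registry
data want three things at once: accuracy beyond any single lightweight
model, honest handling of the rare peak/trough days that matter most for
resource planning, and explanations a clinical audience will accept.
`stackcast` packages that workflow end to end and ships a study-shaped
synthetic panel generator, so the entire pipeline is testable without access
to any registry.

## The method

**Design.** Day *t* is predicted from days *t−1..t−6*: single-day lags plus
moving mean/SD of the admission count and of ten environmental series
(PM2.5, PM10, PMc, SO2, NO2, CO, O3, AQI, TEM, RH), plus calendar features
(day-of-week, month, season, year, timestamp, holiday/workday flags).
Categorical codes are one-hot expanded and continuous columns min–max scaled
(X′ = (X − min X)/(max X − min X)), all fitted on the chronological training
years only.

**Stacking.** Four heterogeneous base learners — ridge, random forest,
gradient-boosted trees, feedforward network — are trained under
chronological 5-fold cross-validation (4 × 5 = 20 fits). Learner *j*'s
out-of-fold predictions M_j on the training rows, and the average N_j of its
five fold models on the test rows, become meta features. An elastic net is
then fitted on (M_1..M_4, key features), where the key features are the
calendar and admission-lag columns, and scores (N_1..N_4, key features).

**LDS weights.** Within each calendar year the label histogram (bin width
1 count) is convolved with a symmetric kernel (default Gaussian, size 5,
σ = 2); each training day is weighted by the inverse of this *effective*
label density, rescaled to mean 1. Rare peak/trough days count more in the
meta learner's loss.

**Evaluation.** MAE, RMSE, MAPE (as a fraction) and R², with paired
two-sided t-tests on per-day losses between models.

**Explanation.** Permutation-estimated Shapley values on the original
feature columns through the whole pipeline; per-variable aggregation (all
`TEM …` columns into TEM); a three-part additive decomposition of every
forecast — base value φ₀ + regular part (calendar + admission history) +
volatile part (environment) — plus global importance rankings, local
waterfalls, and dependence exports. φ₀ + Σ attributions reconstructs each
prediction to 1e-6 relative tolerance by construction.

## Worked example

```bash
python examples/03_train_stacked_model.py
```

prints (seed 0, ~3 minutes on one CPU):

```
base-learner fits performed: 20

         model      MAE     RMSE     MAPE       R2
         Ridge   17.317   23.178    0.192    0.565
            RF   18.970   25.730    0.213    0.464
          GBDT   18.816   24.528    0.232    0.513
           ANN   18.530   24.179    0.203    0.527
Stacking + LDS   16.133   21.581    0.203    0.623
```

The stacked model with LDS beats every base learner on MAE, RMSE and R²:
the elastic net blends the learners' strengths, and the per-year LDS weights
keep the rare winter peaks and holiday troughs from being averaged away
(they also carry the year-on-year trend into the test year). On this
synthetic panel roughly a quarter of the count variance is irreducible
noise, which bounds the attainable R².

`examples/01`–`05` cover each capability: panel simulation, feature
construction, stacking, LDS weights, and explanation. The same pipeline is
scriptable from a shell:

```bash
stackcast simulate --n-days 1461 --seed 42 --out panel.csv
stackcast run-all --seed 0 --out results/
```

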