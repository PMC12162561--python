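# lagrisk

Tools for analysing the lagged relationship between long-term air-pollution
exposure and cancer incidence at the region-year level, and for predicting
incidence from the exposure history despite severe multicollinearity among
the lagged exposure variables.

The intended users are environmental epidemiologists working with panels of
the form *(region, year, lag0…lag9 exposure, incidence)*, where `lagL` is the
annual-mean PM₂.₅ concentration (μg/m³) L calendar years before the outcome
year and incidence is in cases per 100,000. Because ten consecutive annual
means of the same pollutant in the same place are nearly collinear
(adjacent-lag correlations ≈ 0.95, variance inflation factors far above 10),
naive multiple regression is unstable; `lagrisk` provides the standard
remedy chain end to end:

1. **Association screening** — per-lag correlation with a Shapiro–Wilk
   normality gate (Pearson's *r* when both variables pass at α = 0.05,
   Spearman's ρ otherwise) and Deng's grey relational analysis. The grey
   relational degree of lag *i* is the mean over time points of
   ξᵢ(t) = (Δmin + ρ·Δmax) / (Δᵢ(t) + ρ·Δmax),
   with Δᵢ(t) the pointwise deviation between normalized series and
   resolution coefficient ρ = 0.5.
2. **Collinearity diagnostics** — correlation matrix, VIFⱼ = 1/(1 − R²ⱼ),
   tolerance = 1/VIF, and the eigenvalue spectrum of the predictor
   correlation matrix with condition indices √(λmax/λⱼ).
3. **Collinearity-robust predictors** — ridge regression
   β(k) = (XᵀX + kI)⁻¹Xᵀy on standardized data with its ridge trace and
   ridge-adjusted VIFs; ε-insensitive SVR with kernel selection over
   {linear, sigmoid, RBF, polynomial} and permutation feature importance;
   and a 10→h→h→h→1 ReLU feed-forward network with the hidden width h
   chosen on a hold-out split over 5…20.
4. **Combination forecasting** — the three fits are fused by a weighted
   average with weights from the standard-deviation, reciprocal-variance or
   optimal scheme (w = Ω⁻¹1 / 1ᵀΩ⁻¹1, minimizing the combined error's
   quadratic form over the error moment matrix Ω), all evaluated by MAE,
   MSE, MAPE and Theil's U1 inequality coefficient.

A synthetic panel generator with known lag weights (AR(1) annual exposure
series, sliding 10-year windows) reproduces the near-normal marginals and
severe collinearity of real panels, so every stage is testable offline with
ground truth.

## Worked example

```python
import lagrisk as lr

panel, incidence, truth = lr.generate_dataset(lr.SynthConfig(seed=1))

rep = lr.diagnose(panel)
print(f"max VIF {rep.vif.max():.2f}; lags flagged: {rep.high_vif}")

res = lr.RidgeLagModel(panel, incidence).fit(k=100.0)
print(res.summary())
```

prints

```
max VIF 19.87; lags flagged: ['lag0', 'lag1', 'lag2', 'lag3', 'lag4', 'lag5', 'lag6', 'lag7', 'lag8']
ridge fit on 150 region-years
  MAE      1.4640   MSE     3.2577
  MAPE    1.9563%   Theil U 0.0118   R² 0.9400
  ridge k = 100
   lag0  beta* +0.0779   mVIF    0.197
   ...
   lag9  beta* +0.1387   mVIF    0.237
```

— the generator's high inter-annual autocorrelation (0.95) yields the
severe-collinearity regime (VIF > 10 for nine of ten lags), and the
penalized fit explains 94 % of the incidence variance with relative errors
around 2 %; the ridge-adjusted VIFs at k = 100 are all far below 5.
The full pipeline (association → collinearity → three models → ensemble)
runs from the command line:

```bash
lagrisk synth --seed 7 --regions 50 --years 5 -o panel.csv
lagrisk ensemble panel.csv --seed 7           # 6-row metrics comparison
lagrisk run --config cfg.yaml --outdir out/   # report.json + CSV tables
```

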