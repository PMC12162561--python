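# Methods

## Problem setting

`lagrisk` models annual cancer incidence (cases per 100,000) in a set of
regions as a function of the ten preceding annual-mean exposure levels
(lag0…lag9, μg/m³) of an air pollutant. Exposure series at one place are
strongly autocorrelated year over year, so the ten lag predictors are
severely collinear; every design choice below follows from that fact.

## Synthetic data generator

Real registry incidence and satellite-derived exposure surfaces for panels
of this kind are typically not redistributable, so the package carries a
generator whose output has the same statistical structure and a known
ground truth.

For each region an annual exposure series of length `n_years + 9` is drawn
from a stationary Gaussian AR(1): marginal mean `exposure_mean` (default
50 μg/m³), marginal sd `exposure_sd` (default 8 μg/m³), coefficient
`ar_rho` (default 0.95). The ten lag columns are a sliding 10-year window
over this series, which gives two properties the analysis depends on:

* geometrically decaying inter-lag correlation, corr(lagᵢ, lagⱼ) ≈
  ρ^|i−j| — adjacent lags at ≈ 0.95, lags five apart at ≈ 0.77, the
  pattern observed in real multi-year exposure panels; and
* the sliding-window identity lagL(year y) = lag(L−1)(year y−1), which
  tests exploit as a construction invariant.

Incidence is `intercept + Σ_L w_L·lagL + N(0, noise_sd)`, floored at zero.
The default weights (0.05, 0.05, 0.05, 0.15, 0.20, 0.10, 0.05, 0.10, 0.15,
0.25 per μg/m³) put most mass on the distal lags, emulating a long-latency
exposure-response; the default intercept is 20 per 100,000 and the default
noise sd 2 per 100,000, roughly a quarter of the exposure-driven signal sd.
The default panel is 30 regions × 5 outcome years. Exposures are clipped
at a 1 μg/m³ floor (clipping is logged and can be promoted to an error);
with the default mean/sd clipping never triggers.

One master seed drives two independent sub-streams (exposure, incidence
noise), so a panel can be re-noised without changing the exposures. Output
is bit-reproducible given (config, seed).

What the generator does **not** emulate: spatial correlation between
regions, population size and age structure (incidence is treated as a
continuous rate, not a count), measurement error in the exposure
surfaces, and secular trends in either variable. Passing tests therefore
demonstrate correctness of the computations and recoverability under the
stated noise model, not performance on real registry data.

## Association screening

Each lag column is tested against incidence after a Shapiro–Wilk normality
gate at α = 0.05 on both variables (Pearson if both pass, Spearman
otherwise; two-sided p-values, no multiple-testing correction — this stage
is exploratory screening, not confirmatory inference).

Grey relational analysis (Deng's degree) is computed with resolution
coefficient ρ = 0.5, the conventional choice in the grey-systems
literature; ρ bounds every relational coefficient below by ρ/(1+ρ) = 1/3.
Series are normalized by their mean by default (dividing by the series
mean), which makes the degree invariant to common positive rescaling of
all series; `initial` and `minmax` schemes are available as parameters
because reported grey relational tables in the applied literature rarely
state their normalization. Grouped output uses the cross-region incidence
within one year as the reference (one column per year) plus a pooled
"overall" column over all region-years. If all series are identical after
normalization (Δmax = 0) the degree is defined as 1.

## Collinearity diagnostics

VIF_j = 1/(1 − R²_j) is computed as the j-th diagonal of the inverse
predictor correlation matrix; if that matrix is singular (exactly
collinear columns) the implementation falls back to per-column
least-squares regressions and reports VIF = ∞ with a flag instead of
failing. Tolerance is 1/VIF. Eigenvalues and condition indices
√(λmax/λⱼ) come from the 10×10 predictor correlation matrix by default —
the most reproducible convention because it is scale-free. An alternative
convention (cross-product of the intercept-augmented, unit-length-scaled
design, giving 11 indices) is available via `convention="augmented"`;
under it the trailing dimensions collapse toward zero eigenvalues and
condition indices above 30, as expected for this data structure.
Thresholds: VIF > 10 and condition index > 30 are flagged as severe.

## Ridge regression

Predictors and response are standardized to zero mean and unit sample sd
(ddof = 1), so XᵀX = (n−1)R. Coefficients are the dense solve
β(k) = (XᵀX + kI)⁻¹Xᵀy; predictions are back-transformed to the original
scale. The penalty k is therefore **scale-dependent**: a k chosen on one
dataset (or under another standardization convention) does not transfer,
and should be read off the ridge trace, the path of β(k) over an
ascending grid, on which the standardized in-sample MSE is non-decreasing
and the coefficient norm non-increasing in k.

The ridge-adjusted VIF is
mVIF_j(k) = [(XᵀX+kI)⁻¹ XᵀX (XᵀX+kI)⁻¹]_jj · (n−1),
the variance inflation of the ridge estimator on correlation-scaled data;
at k = 0 it equals the ordinary VIF exactly.

## Support vector regression

ε-insensitive SVR (scikit-learn) on standardized inputs and response.
Defaults: C = 1, ε = 0.1, RBF bandwidth γ = 'scale' (1/(10·feature
variance)), polynomial degree 3 — all exposed in configuration, since no
single default suits every panel. Kernel selection fits all four kernels
and takes minimal in-sample MSE, with ties broken by higher R² and then
kernel order. Feature importance is permutation importance (mean MSE
increase over seeded permutations of one standardized column at a time),
chosen because RBF SVR has no native coefficients; it is exact zero for a
constant column and deterministic given the seed.

## Feed-forward network

Architecture 10 → h → h → h → 1 with ReLU hidden activations and a linear
output; the same width h in all three hidden layers. Training is
full-batch adam (an adaptive-learning-rate gradient method) for a fixed
budget of 2000 epochs at initial learning rate 0.01, with scikit-learn's
default He-style initialization under the given seed and no early
stopping, so runs are deterministic. The width is selected over a 5…20
grid by MSE on a seeded 20% hold-out split, then the selected network is
refit on all rows; a width whose training diverges (non-finite loss) is
skipped with a warning. These training constants are deliberate defaults
for 10-input panels with tens to hundreds of rows, all exposed in
`NetworkTrainingConfig`.

## Combination forecast

With in-sample errors e_i(t) per model, Ω_ij = (1/n)Σ_t e_i(t)e_j(t) is
the raw (not mean-centered) second-moment matrix, so Ω_ii is exactly
MSE_i and, because weights sum to 1, the combined MSE is exactly wᵀΩw.
Three schemes:

* standard deviation: w_i = (S − S_i)/((m−1)S), S_i = √Ω_ii, S = ΣS_j;
* reciprocal variance: w_i ∝ 1/Ω_ii (weight 1 on a perfect model, with a
  warning);
* optimal: w = Ω⁻¹1/(1ᵀΩ⁻¹1), the exact minimizer of wᵀΩw under Σw = 1.
  Negative weights are permitted (the unconstrained-sign optimum); when Ω
  is singular the minimizer over the probability simplex is found by a
  dense grid search at step 10⁻³ (ties resolved to the centroid of the
  tied set, which by convexity is also a minimizer), with a warning.

Since each unit vector is feasible, the optimal combination's in-sample
MSE can never exceed the best single model's — the qualitative pattern
combination forecasting exists to deliver.

## Evaluation

All models and combinations are scored by one routine: MAE, MSE,
MAPE = 100·mean(|y−ŷ|/|y|) (undefined and flagged when any observation is
zero), and Theil's U1 = RMSE/(√mean y² + √mean ŷ²) ∈ [0,1]. U1 was chosen
over the unbounded U2 because a bounded inequality coefficient is the
natural companion to percentage errors in the 5–15% range; U2 is
available behind a flag.

## Pipeline and reproducibility

The pipeline derives all stage seeds (synthetic data, network training,
permutation importance) from one global seed via seed-sequence spawning,
embeds a hash of the scientific configuration in the JSON report
(excluding the output location), and writes sorted-key JSON, so a rerun
with the same configuration is byte-identical. Problem sizes used in the
test suite and acceptance script — 15–30 regions × 5 years for pipeline
runs, 200 regions for oracle comparisons, 500 regions for parameter
recovery, trimmed node grids where the full 5…20 sweep adds nothing to
the property under test — were chosen as the smallest panels at which
each property is stable across seeds.

## Known limitations

* In-sample evaluation throughout (mirroring the combination-forecast
  setting, where weights are derived from in-sample error moments); an
  optional hold-out exists only inside the network's width selection.
* The grey relational normalization and grouping conventions materially
  affect the degrees; published tables rarely state them, so
  cross-package comparisons of absolute degrees are unreliable.
* No spatial structure, population weighting, or count-model likelihood;
  incidence is treated as a Gaussian-noise continuous rate.
* Ridge k is scale-dependent by construction; compare k values only
  within one standardization convention.
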