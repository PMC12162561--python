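"""Collinearity-robust predictors of incidence from lagged exposure.

Three single models, each wrapped as a Model class whose ``fit`` returns
a Results object carrying in-sample predictions and the shared MetricSet
(computed by :mod:`lagrisk.evaluation` — no per-model metric code):

* :class:`RidgeLagModel` — ridge regression on standardized data,
  β(k) = (XᵀX + kI)⁻¹Xᵀy, with the ridge trace over a k-grid and the
  ridge-adjusted VIF
  mVIF_j(k) = [(XᵀX+kI)⁻¹ XᵀX (XᵀX+kI)⁻¹]_jj · (n−1),
  which reduces to the ordinary VIF at k = 0 (on sample-standardized X,
  XᵀX = (n−1)R).
* :class:`KernelSVRModel` — ε-insensitive support-vector regression on
  standardized inputs; :meth:`select` compares the four classical
  kernels (linear, sigmoid, RBF, polynomial) by in-sample MSE (ties by
  higher R², then kernel order) and permutation importance scores the
  lags of the chosen fit.
* :class:`LagNetworkModel` — a small feed-forward network
  (10 → h → h → h → 1, ReLU hidden units, linear output) trained
  full-batch with an adaptive-learning-rate gradient optimizer; the
  hidden width h is chosen on a hold-out split over a 5..20 grid, then
  the network is refit on all rows.

Models are fit in-sample by design: the use case is explaining and
reconstructing observed incidence from the exposure history, and the
combination-forecast layer weights models by their in-sample error
moments. ``holdout`` options exist where generalization is the question.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .evaluation import MetricSet, metrics
from .panel import LAG_COLUMNS, N_LAGS, align

logger = logging.getLogger(__name__)

SVR_KERNELS = ("linear", "sigmoid", "rbf", "poly")
DEFAULT_NODE_GRID = tuple(range(5, 21))


def _standardize(A: np.ndarray):
    """Zero-mean, unit-sample-sd columns (ddof=1), so XᵀX = (n−1)·R.

    A constant column standardizes to all zeros (it carries no signal);
    models that cannot tolerate that (ridge at k = 0) fail on the
    resulting singular system with a clear error.
    """
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    safe_sd = np.where(sd == 0, 1.0, sd)
    return (A - mean) / safe_sd, mean, safe_sd


class _LagModelBase:
    """Shared data handling: align panel + incidence, standardize."""

    def __init__(self, panel: pd.DataFrame, incidence: pd.DataFrame):
        data = align(panel, incidence)
        self.data = data
        self.keys = data[["region_id", "year"]]
        self.X = data[LAG_COLUMNS].to_numpy(dtype=float)
        self.y = data["incidence"].to_numpy(dtype=float)
        self.n = len(data)
        self.Xs, self.x_mean, self.x_sd = _standardize(self.X)
        if self.y.std(ddof=1) == 0:
            raise ValueError("degenerate response: incidence has zero variance")
        self.ys = (self.y - self.y.mean()) / self.y.std(ddof=1)


@dataclass
class FitResults:
    """Base results: observed vs. predicted plus the shared MetricSet."""

    model_name: str
    observed: np.ndarray = field(repr=False)
    predictions: np.ndarray = field(repr=False)
    keys: pd.DataFrame = field(repr=False)
    metric_set: MetricSet = None

    def __post_init__(self):
        if self.metric_set is None:
            self.metric_set = metrics(self.observed, self.predictions)

    @property
    def mse(self) -> float:
        return self.metric_set.mse

    @property
    def r2(self) -> float:
        sst = float(np.sum((self.observed - self.observed.mean()) ** 2))
        sse = float(np.sum((self.observed - self.predictions) ** 2))
        return 1.0 - sse / sst

    def prediction_table(self) -> pd.DataFrame:
        tab = self.keys.copy()
        tab["observed"] = self.observed
        tab["predicted"] = self.predictions
        with np.errstate(divide="ignore", invalid="ignore"):
            tab["relative_error"] = np.abs(self.observed - self.predictions) / np.abs(self.observed)
        return tab

    def summary(self) -> str:
        m = self.metric_set
        lines = [
            f"{self.model_name} fit on {m.n} region-years",
            f"  MAE  {m.mae:10.4f}   MSE {m.mse:10.4f}",
            f"  MAPE {m.mape:9.4f}%   Theil U {m.theil_u:.4f}   R² {self.r2:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"model": self.model_name, "metrics": self.metric_set.to_dict(),
                "r2": self.r2}


# --------------------------------------------------------------------------
# Ridge regression
# --------------------------------------------------------------------------

@dataclass
class RidgeResults(FitResults):
    """Ridge fit at one k: standardized coefficients + adjusted VIFs."""

    k: float = 0.0
    coefficients: pd.Series = None  # standardized scale
    intercept: float = 0.0  # original scale
    coefficients_original: pd.Series = None  # per μg/m³, original scale
    modified_vif: pd.Series = None
    mse_standardized: float = 0.0

    def summary(self) -> str:
        base = super().summary()
        coef = "\n".join(
            f"  {lag:>5}  beta* {b:+.4f}   mVIF {v:8.3f}"
            for lag, b, v in zip(self.coefficients.index, self.coefficients,
                                 self.modified_vif)
        )
        return f"{base}\n  ridge k = {self.k:g}\n{coef}"

    def to_dict(self) -> dict:
        d = super().to_dict()
        d.update(
            k=self.k,
            intercept=self.intercept,
            coefficients_standardized=self.coefficients.to_dict(),
            coefficients_original=self.coefficients_original.to_dict(),
            modified_vif=self.modified_vif.to_dict(),
        )
        return d


class RidgeLagModel(_LagModelBase):
    """Ridge regression of incidence on the ten standardized lag columns."""

    def fit(self, k: float = 0.0) -> RidgeResults:
        if not np.isfinite(k) or k < 0:
            raise ValueError(f"ridge parameter k must be finite and ≥ 0, got {k}")
        Xs, ys = self.Xs, self.ys
        G = Xs.T @ Xs + k * np.eye(N_LAGS)
        try:
            Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular ridge system at k={k}: exactly collinear or constant "
                "lag columns; use k > 0"
            ) from exc
        beta = Ginv @ (Xs.T @ ys)

        mvif = np.diag(Ginv @ (Xs.T @ Xs) @ Ginv) * (self.n - 1)

        yhat_s = Xs @ beta
        y_sd = self.y.std(ddof=1)
        predictions = self.y.mean() + y_sd * yhat_s

        coef_orig = beta * y_sd / self.x_sd
        intercept = float(self.y.mean() - coef_orig @ self.x_mean)

        return RidgeResults(
            model_name="ridge",
            observed=self.y,
            predictions=predictions,
            keys=self.keys,
            k=float(k),
            coefficients=pd.Series(beta, index=LAG_COLUMNS),
            intercept=intercept,
            coefficients_original=pd.Series(coef_orig, index=LAG_COLUMNS),
            modified_vif=pd.Series(mvif, index=LAG_COLUMNS),
            mse_standardized=float(np.mean((ys - yhat_s) ** 2)),
        )

    def trace(self, k_grid) -> pd.DataFrame:
        """Ridge trace: coefficients, standardized MSE and max mVIF along k.

        The grid is sorted ascending (with a warning if it was not); the
        standardized in-sample MSE is non-decreasing and the coefficient
        norm non-increasing along it.
        """
        k_grid = [float(k) for k in k_grid]
        if not k_grid:
            raise ValueError("empty k grid")
        if any(k < 0 for k in k_grid):
            raise ValueError("ridge parameters must be ≥ 0")
        if k_grid != sorted(k_grid):
            logger.warning("unsorted ridge k grid; sorting ascending")
            k_grid = sorted(k_grid)
        rows = []
        for k in k_grid:
            res = self.fit(k)
            row = {"k": k, "mse_standardized": res.mse_standardized,
                   "mse": res.mse, "coef_norm": float(np.linalg.norm(res.coefficients)),
                   "max_modified_vif": float(res.modified_vif.max())}
            row.update({f"beta_{lag}": res.coefficients[lag] for lag in LAG_COLUMNS})
            rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Support vector regression
# --------------------------------------------------------------------------

@dataclass
class SVRResults(FitResults):
    kernel: str = "rbf"
    hyperparameters: dict = field(default_factory=dict)
    kernel_comparison: pd.DataFrame = field(default=None, repr=False)
    importance: pd.Series = None

    def to_dict(self) -> dict:
        d = super().to_dict()
        d.update(kernel=self.kernel, hyperparameters=dict(self.hyperparameters))
        if self.importance is not None:
            d["importance"] = self.importance.to_dict()
        return d


class KernelSVRModel(_LagModelBase):
    """ε-insensitive SVR on standardized lag columns.

    Default hyperparameters: C = 1.0, ε = 0.1, γ = 'scale'
    (1/(n_features · var(X)), i.e. bandwidth tied to the pooled feature
    variance), polynomial degree 3.
    """

    def __init__(self, panel, incidence, C: float = 1.0, epsilon: float = 0.1,
                 gamma="scale", degree: int = 3):
        super().__init__(panel, incidence)
        self.C, self.epsilon, self.gamma, self.degree = C, epsilon, gamma, degree
        self._estimators: dict[str, SVR] = {}

    def _hyper(self) -> dict:
        return {"C": self.C, "epsilon": self.epsilon, "gamma": self.gamma,
                "degree": self.degree}

    def fit(self, kernel: str = "rbf") -> SVRResults:
        if kernel not in SVR_KERNELS:
            raise ValueError(f"kernel must be one of {SVR_KERNELS}, got {kernel!r}")
        est = SVR(kernel=kernel, C=self.C, epsilon=self.epsilon,
                  gamma=self.gamma, degree=self.degree)
        est.fit(self.Xs, self.ys)
        self._estimators[kernel] = est
        y_sd = self.y.std(ddof=1)
        predictions = self.y.mean() + y_sd * est.predict(self.Xs)
        return SVRResults(
            model_name=f"svr_{kernel}",
            observed=self.y,
            predictions=predictions,
            keys=self.keys,
            kernel=kernel,
            hyperparameters=self._hyper(),
        )

    def select(self, kernels=SVR_KERNELS) -> SVRResults:
        """Fit every kernel, compare by MSE (ties: higher R², then order)."""
        fits = {k: self.fit(k) for k in kernels}
        comparison = pd.DataFrame(
            {"kernel": list(kernels),
             "mse": [fits[k].mse for k in kernels],
             "r2": [fits[k].r2 for k in kernels]}
        )
        best = min(fits.values(), key=lambda f: (f.mse, -f.r2, list(kernels).index(f.kernel)))
        best.model_name = "svr"
        best.kernel_comparison = comparison
        return best

    def permutation_importance(self, results: SVRResults, n_repeats: int = 30,
                               seed: int = 0) -> pd.Series:
        """Per-lag permutation importance: mean MSE increase when a lag is shuffled."""
        if n_repeats < 1:
            raise ValueError("n_repeats must be ≥ 1")
        est = self._estimators.get(results.kernel)
        if est is None:
            raise ValueError("results were not produced by this model instance")
        rng = np.random.default_rng(seed)
        y_sd, y_mean = self.y.std(ddof=1), self.y.mean()
        baseline = results.mse
        scores = np.zeros(N_LAGS)
        for j in range(N_LAGS):
            for _ in range(n_repeats):
                Xp = self.Xs.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                pred = y_mean + y_sd * est.predict(Xp)
                scores[j] += metrics(self.y, pred).mse - baseline
        importance = pd.Series(scores / n_repeats, index=LAG_COLUMNS, name="importance")
        results.importance = importance
        return importance


# --------------------------------------------------------------------------
# Feed-forward network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkTrainingConfig:
    """Training knobs for the feed-forward network.

    epochs: full-batch passes of the adaptive-rate optimizer (adam);
    learning_rate: initial step size; holdout_fraction: share of rows
    held out for the node-count selection split.
    """

    epochs: int = 2000
    learning_rate: float = 0.01
    holdout_fraction: float = 0.2

    def __post_init__(self):
        if self.epochs < 1 or not (0 < self.holdout_fraction < 1) or self.learning_rate <= 0:
            raise ValueError("invalid network training configuration")


@dataclass
class NetworkResults(FitResults):
    selected_nodes: int = 0
    node_grid: tuple = ()
    validation_mse: pd.Series = None  # per candidate h (standardized scale)
    seed: int = 0
    training: NetworkTrainingConfig = None

    def to_dict(self) -> dict:
        d = super().to_dict()
        d.update(
            architecture=f"10-{self.selected_nodes}-{self.selected_nodes}-{self.selected_nodes}-1",
            selected_nodes=self.selected_nodes,
            node_grid=list(self.node_grid),
            validation_mse={int(k): (None if np.isnan(v) else float(v))
                            for k, v in self.validation_mse.items()},
            seed=self.seed,
        )
        return d


class LagNetworkModel(_LagModelBase):
    """10 → h → h → h → 1 ReLU network with hidden-width selection.

    For each candidate h the network is trained on a seeded 80/20 split
    and scored on the held-out rows; the h with minimal validation MSE
    (ties: first in grid order) is refit on all rows. Deterministic
    given (seed, training config).
    """

    def _make_estimator(self, h: int, seed: int, config: NetworkTrainingConfig,
                        n_rows: int) -> MLPRegressor:
        return MLPRegressor(
            hidden_layer_sizes=(h, h, h),
            activation="relu",
            solver="adam",
            batch_size=n_rows,  # full batch
            learning_rate_init=config.learning_rate,
            max_iter=config.epochs,
            tol=0.0,
            n_iter_no_change=config.epochs,  # never stop early
            shuffle=False,
            random_state=seed % (2**31),
        )

    def fit(self, node_grid=DEFAULT_NODE_GRID, seed: int = 0,
            training: NetworkTrainingConfig | None = None) -> NetworkResults:
        training = training or NetworkTrainingConfig()
        node_grid = tuple(int(h) for h in node_grid)
        if not node_grid or any(h < 1 for h in node_grid):
            raise ValueError("node grid must be non-empty positive widths")

        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.n)
        n_val = max(1, int(round(self.n * training.holdout_fraction)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) < 1:
            raise ValueError("holdout fraction leaves no training rows")

        val_mse = {}
        import warnings

        for h in node_grid:
            est = self._make_estimator(h, seed, training, len(train_idx))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(self.Xs[train_idx], self.ys[train_idx])
            pred = est.predict(self.Xs[val_idx])
            m = float(np.mean((self.ys[val_idx] - pred) ** 2))
            if not np.isfinite(m):
                logger.warning("non-finite validation loss at h=%d; skipping", h)
                m = np.nan
            val_mse[h] = m

        finite = {h: m for h, m in val_mse.items() if np.isfinite(m)}
        if not finite:
            raise RuntimeError("training diverged for every candidate width")
        best_h = min(finite, key=lambda h: (finite[h], node_grid.index(h)))

        est = self._make_estimator(best_h, seed, training, self.n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(self.Xs, self.ys)
        y_sd = self.y.std(ddof=1)
        predictions = self.y.mean() + y_sd * est.predict(self.Xs)

        return NetworkResults(
            model_name="network",
            observed=self.y,
            predictions=predictions,
            keys=self.keys,
            selected_nodes=best_h,
            node_grid=node_grid,
            validation_mse=pd.Series(val_mse),
            seed=seed,
            training=training,
        )


# --------------------------------------------------------------------------
# Thin functional surface
# --------------------------------------------------------------------------

def ridge_fit(panel, incidence, k: float = 0.0) -> RidgeResults:
    return RidgeLagModel(panel, incidence).fit(k)


def ridge_trace(panel, incidence, k_grid) -> pd.DataFrame:
    return RidgeLagModel(panel, incidence).trace(k_grid)


def svr_select(panel, incidence, kernels=SVR_KERNELS, **hyper) -> SVRResults:
    return KernelSVRModel(panel, incidence, **hyper).select(kernels)


def feature_importance(fit: SVRResults, panel, incidence, n_repeats: int = 30,
                       seed: int = 0) -> pd.Series:
    """Permutation importance of each lag for a (re-trained) SVR fit."""
    model = KernelSVRModel(panel, incidence, **fit.hyperparameters)
    refit = model.fit(fit.kernel)
    return model.permutation_importance(refit, n_repeats=n_repeats, seed=seed)


def network_fit(panel, incidence, node_grid=DEFAULT_NODE_GRID, seed: int = 0,
                training: NetworkTrainingConfig | None = None) -> NetworkResults:
    return LagNetworkModel(panel, incidence).fit(node_grid, seed, training)
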