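"""Combination forecasting: weight single models and fuse their predictions.

Given m single models with in-sample error series e_i(t) = y(t) − ŷ_i(t),
the second-moment error matrix Ω_ij = (1/n)Σ_t e_i(t)e_j(t) (not
mean-centered, so Ω_ii is exactly MSE_i) drives three weighting schemes:

* ``std_dev`` — w_i = (S − S_i) / ((m−1)·S) with S_i = sqrt(Ω_ii),
  S = Σ_j S_j: smaller-error models get larger (always nonnegative)
  weights.
* ``inv_variance`` — w_i ∝ 1/Ω_ii: precision weighting, optimal when
  errors are uncorrelated.
* ``optimal`` — w = Ω⁻¹1 / (1ᵀΩ⁻¹1), the minimizer of the combined
  in-sample MSE wᵀΩw subject to Σw = 1; weights may be negative. When Ω
  is singular the minimizer over the probability simplex is found by
  dense grid search (step 1e-3) instead, with a logged warning.

Because Σw = 1, the combined error is Σ_i w_i e_i(t), so the optimal
scheme's combined MSE equals wᵀΩw exactly and can never exceed the best
single model's MSE (each unit vector is feasible).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEIGHT_METHODS = ("std_dev", "inv_variance", "optimal")


@dataclass
class ErrorMatrix:
    """Per-model error series and their second-moment matrix Ω."""

    models: tuple
    errors: np.ndarray = field(repr=False)  # shape (m, n)
    omega: np.ndarray = field(repr=False)  # shape (m, m)

    @classmethod
    def from_predictions(cls, observed, predictions: dict) -> "ErrorMatrix":
        """Build from aligned series: predictions maps model name → series."""
        y = np.asarray(observed, dtype=float)
        names = tuple(predictions)
        if len(names) < 2:
            raise ValueError("need at least 2 models to combine")
        errs = []
        for name in names:
            p = np.asarray(predictions[name], dtype=float)
            if p.shape != y.shape:
                raise ValueError(f"predictions for {name!r} not aligned with observations")
            errs.append(y - p)
        E = np.vstack(errs)
        omega = E @ E.T / y.size
        return cls(models=names, errors=E, omega=omega)

    @property
    def mse(self) -> pd.Series:
        return pd.Series(np.diag(self.omega), index=self.models, name="MSE")


@dataclass(frozen=True)
class EnsembleWeights:
    method: str
    weights: pd.Series

    def __post_init__(self):
        s = float(self.weights.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {s}")

    def to_dict(self) -> dict:
        return {"method": self.method, "weights": {k: float(v) for k, v in self.weights.items()}}


def _simplex_grid_minimizer(omega: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Dense grid search of min wᵀΩw over the probability simplex."""
    m = omega.shape[0]
    n_steps = int(round(1.0 / step))
    if m == 2:
        w0 = np.linspace(0.0, 1.0, n_steps + 1)
        W = np.column_stack([w0, 1.0 - w0])
    elif m == 3:
        pts = []
        for i in range(n_steps + 1):
            a = i * step
            b = np.linspace(0.0, 1.0 - a, n_steps + 1 - i)
            pts.append(np.column_stack([np.full_like(b, a), b, 1.0 - a - b]))
        W = np.vstack(pts)
    else:  # coarse recursive enumeration for m > 3 (rare)
        coarse = 0.02
        ticks = int(round(1.0 / coarse))
        combos = [c for c in itertools.product(range(ticks + 1), repeat=m - 1)
                  if sum(c) <= ticks]
        W = np.array([[i * coarse for i in c] + [1.0 - coarse * sum(c)] for c in combos])
    vals = np.einsum("ij,jk,ik->i", W, omega, W)
    vmin = vals.min()
    # the minimizing set is convex, so the centroid of (near-)tied grid points
    # is itself a minimizer; for flat minima (e.g. identical models) this
    # restores the symmetric solution exactly
    ties = W[vals <= vmin + 1e-9 * max(1.0, abs(vmin))]
    return ties.mean(axis=0)


def compute_weights(errors: ErrorMatrix, method: str) -> EnsembleWeights:
    """One of the three weighting schemes applied to an error matrix."""
    if method not in WEIGHT_METHODS:
        raise ValueError(f"method must be one of {WEIGHT_METHODS}, got {method!r}")
    omega = errors.omega
    m = omega.shape[0]
    mse = np.diag(omega)

    if method == "std_dev":
        s = np.sqrt(mse)
        total = s.sum()
        if total == 0:  # all models perfect: any convex weights are optimal
            w = np.full(m, 1.0 / m)
        else:
            w = (total - s) / ((m - 1) * total)
    elif method == "inv_variance":
        if (mse == 0).any():
            logger.warning("perfect model present; inv_variance puts weight 1 on it")
            w = np.zeros(m)
            w[int(np.argmin(mse))] = 1.0
        else:
            inv = 1.0 / mse
            w = inv / inv.sum()
    else:  # optimal
        ones = np.ones(m)
        try:
            oinv_1 = np.linalg.solve(omega, ones)
            denom = ones @ oinv_1
            if not np.isfinite(oinv_1).all() or abs(denom) < 1e-300:
                raise np.linalg.LinAlgError("degenerate solve")
            w = oinv_1 / denom
        except np.linalg.LinAlgError:
            logger.warning("singular error moment matrix; falling back to simplex grid search")
            w = _simplex_grid_minimizer(omega)

    return EnsembleWeights(method=method, weights=pd.Series(w, index=errors.models))


def combine(predictions: dict, weights: EnsembleWeights) -> np.ndarray:
    """Weighted average of aligned prediction series, Σ_i w_i·ŷ_i(t)."""
    names = list(weights.weights.index)
    missing = [n for n in names if n not in predictions]
    if missing:
        raise ValueError(f"missing predictions for weighted model(s): {missing}")
    arrays = [np.asarray(predictions[n], dtype=float) for n in names]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("prediction series are not aligned")
    return np.einsum("i,ij->j", weights.weights.to_numpy(), np.vstack(arrays))
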