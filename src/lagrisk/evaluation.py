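"""Forecast accuracy metrics: MAE, MSE, MAPE and Theil's U.

All model fits and ensemble combinations in this package are scored by
the single :func:`metrics` function so that every reported MetricSet is
computed by identical code.

Theil's U defaults to the bounded U1 inequality coefficient,

    U1 = RMSE / (sqrt(mean y²) + sqrt(mean ŷ²)) ∈ [0, 1],

with 0 a perfect forecast and 1 the worst case (e.g. predicting 0 for a
positive series). The unbounded U2 relative-accuracy variant is
available behind ``variant="u2"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricSet:
    """The four accuracy metrics on one (observed, predicted) pair.

    ``mape`` is NaN with ``mape_undefined`` set when any observation is
    zero (percentage error undefined); the other metrics are still
    computed.
    """

    mae: float
    mse: float
    mape: float  # percent
    theil_u: float
    n: int
    mape_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "MAE": self.mae,
            "MSE": self.mse,
            "MAPE_percent": None if self.mape_undefined else self.mape,
            "TheilU": self.theil_u,
            "n": self.n,
        }


def metrics(observed, predicted, variant: str = "u1") -> MetricSet:
    """Compute MAE, MSE, MAPE (%) and Theil's U for aligned series."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("observed and predicted must be aligned 1-D series, n ≥ 1")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("non-finite values in observed or predicted series")

    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))

    mape_undefined = bool((y == 0).any())
    mape = math.nan if mape_undefined else float(100.0 * np.mean(np.abs(err) / np.abs(y)))

    rmse = math.sqrt(mse)
    if variant == "u1":
        denom = math.sqrt(float(np.mean(y**2))) + math.sqrt(float(np.mean(yhat**2)))
        theil_u = 0.0 if denom == 0.0 else rmse / denom
    elif variant == "u2":
        denom = math.sqrt(float(np.mean(y**2)))
        theil_u = math.inf if denom == 0.0 and rmse > 0 else (0.0 if denom == 0.0 else rmse / denom)
    else:
        raise ValueError(f"unknown Theil U variant: {variant!r}")

    return MetricSet(mae=mae, mse=mse, mape=mape, theil_u=theil_u,
                     n=y.size, mape_undefined=mape_undefined)
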