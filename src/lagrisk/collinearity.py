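"""Multicollinearity diagnostics for the ten lag predictors.

The ten lag columns of an exposure panel are near-copies of each other
(adjacent annual means correlate ≈ 0.95), so ordinary least squares is
unstable. This module quantifies that: Pearson correlation matrix,
variance inflation factors (VIF_j = 1/(1 − R²_j) with R²_j from
regressing lag j on the other nine), tolerances (1/VIF), and the
eigenvalue spectrum of the predictor correlation matrix with condition
indices sqrt(λ_max/λ_j). VIF > 10 and condition index > 30 are flagged
as severe collinearity.

By default the spectrum is that of the 10×10 predictor correlation
matrix. ``convention="augmented"`` instead uses the cross-product of the
intercept-augmented, unit-length-scaled design [1|X], which yields 11
eigenvalues/indices — the convention under which dimensions beyond the
first couple collapse to near-zero eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import LAG_COLUMNS, N_LAGS, validate_panel

VIF_THRESHOLD = 10.0
CONDITION_INDEX_THRESHOLD = 30.0

_EXACT_R2_TOL = 1e-12


@dataclass
class CollinearityReport:
    """Correlation, VIF/tolerance and eigen-spectrum diagnostics."""

    correlation: pd.DataFrame
    vif: pd.Series
    tolerance: pd.Series
    eigenvalues: np.ndarray  # descending
    condition_indices: np.ndarray  # aligned with eigenvalues; first = 1
    convention: str = "correlation"
    high_vif: list = field(default_factory=list)
    high_condition_index: int = 0
    exactly_collinear: bool = False

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "vif": {k: (None if np.isinf(v) else float(v)) for k, v in self.vif.items()},
            "tolerance": {k: float(v) for k, v in self.tolerance.items()},
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "condition_indices": [
                None if np.isinf(v) else float(v) for v in self.condition_indices
            ],
            "high_vif": list(self.high_vif),
            "n_condition_indices_over_30": self.high_condition_index,
            "exactly_collinear": self.exactly_collinear,
        }


def _vif_from_r2(r2: float) -> float:
    return np.inf if r2 >= 1.0 - _EXACT_R2_TOL else 1.0 / (1.0 - r2)


def _vif_per_column(X: np.ndarray) -> np.ndarray:
    """VIFs by regressing each column on the others (with intercept)."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst
        out[j] = _vif_from_r2(r2)
    return out


def diagnose(panel: pd.DataFrame, convention: str = "correlation") -> CollinearityReport:
    """Full collinearity diagnosis of a panel's ten lag columns.

    Requires more rows than predictors + 1 and no constant lag column.
    Exactly collinear columns yield VIF = +inf with the
    ``exactly_collinear`` flag raised rather than an error.
    """
    validate_panel(panel)
    X = panel[LAG_COLUMNS].to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows for {p} predictors, got {n}")
    if (X.std(axis=0) == 0).any():
        bad = [LAG_COLUMNS[j] for j in range(p) if X[:, j].std() == 0]
        raise ValueError(f"constant predictor column(s): {', '.join(bad)}")

    corr = np.corrcoef(X, rowvar=False)
    corr_df = pd.DataFrame(corr, index=LAG_COLUMNS, columns=LAG_COLUMNS)

    # VIF = diag(R^-1); fall back to per-column regressions when R is singular
    try:
        rinv = np.linalg.inv(corr)
        vif_vals = np.diag(rinv).copy()
        if (vif_vals < 1.0 - 1e-8).any() or not np.isfinite(vif_vals).all():
            raise np.linalg.LinAlgError("unreliable inverse")
    except np.linalg.LinAlgError:
        vif_vals = _vif_per_column(X)
    vif = pd.Series(vif_vals, index=LAG_COLUMNS, name="VIF")
    with np.errstate(divide="ignore"):
        tolerance = (1.0 / vif).rename("tolerance")

    if convention == "correlation":
        eig = np.linalg.eigvalsh(corr)[::-1]
    elif convention == "augmented":
        A = np.column_stack([np.ones(n), X])
        A = A / np.linalg.norm(A, axis=0)
        eig = np.linalg.eigvalsh(A.T @ A)[::-1]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    eig = np.clip(eig, 0.0, None)
    with np.errstate(divide="ignore"):
        cond_idx = np.sqrt(eig[0] / eig)

    return CollinearityReport(
        correlation=corr_df,
        vif=vif,
        tolerance=tolerance,
        eigenvalues=eig,
        condition_indices=cond_idx,
        convention=convention,
        high_vif=[lag for lag, v in vif.items() if v > VIF_THRESHOLD],
        high_condition_index=int((cond_idx > CONDITION_INDEX_THRESHOLD).sum()),
        exactly_collinear=bool(np.isinf(vif_vals).any()),
    )
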