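"""Per-lag association screening and grey relational analysis.

Two complementary views of how lagged exposure tracks incidence:

* :func:`lag_correlation` — classical univariate screening. Each lag
  column is tested against incidence with Pearson's r when both
  variables pass a Shapiro–Wilk normality gate (p > α on both), and
  Spearman's rank correlation otherwise.
* :func:`grey_relational` — Deng's grey relational degree, a
  normalization-based similarity between a reference series (incidence)
  and comparison series (the lag columns) that does not assume
  linearity or any distribution, suited to the short annual series
  typical of registry data.

The grey relational degree of comparison i is the mean over time points
of the relational coefficient

    ξ_i(t) = (Δmin + ρ·Δmax) / (Δ_i(t) + ρ·Δmax),

where Δ_i(t) = |ref*(t) − comp_i*(t)| on normalized series and
Δmin/Δmax are global over all comparisons and time points. The
resolution coefficient ρ (default 0.5) bounds every coefficient below
by ρ/(1+ρ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import LAG_COLUMNS, align

VALID_NORMALIZATIONS = ("mean", "initial", "minmax")


def normality_test(x) -> tuple[float, float]:
    """Shapiro–Wilk test; returns (W, p).

    Requires n ≥ 3 finite values with nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("normality test needs a 1-D sample with n ≥ 3")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in sample")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def lag_correlation(panel: pd.DataFrame, incidence: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Normality-gated per-lag correlation with incidence.

    Returns a tidy frame with one row per lag: ``lag, method, coefficient,
    p_value, normality_p_exposure, normality_p_incidence``. The method is
    Pearson iff both Shapiro–Wilk p-values exceed ``alpha``, else
    Spearman; p-values are two-sided.
    """
    data = align(panel, incidence)
    if len(data) < 4:
        raise ValueError("need at least 4 aligned rows for correlation")
    y = data["incidence"].to_numpy()
    _, p_inc = normality_test(y)

    rows = []
    for col in LAG_COLUMNS:
        x = data[col].to_numpy()
        _, p_exp = normality_test(x)
        if p_exp > alpha and p_inc > alpha:
            method = "pearson"
            r, p = stats.pearsonr(x, y)
        else:
            method = "spearman"
            r, p = stats.spearmanr(x, y)
        rows.append(
            {
                "lag": col,
                "method": method,
                "coefficient": float(r),
                "p_value": float(p),
                "normality_p_exposure": p_exp,
                "normality_p_incidence": p_inc,
            }
        )
    return pd.DataFrame(rows)


def _normalize(x: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "mean":
        m = x.mean()
        if m == 0:
            raise ValueError("zero-mean series: mean normalization undefined")
        return x / m
    if scheme == "initial":
        if x[0] == 0:
            raise ValueError("zero initial value: initial normalization undefined")
        return x / x[0]
    if scheme == "minmax":
        rng = np.ptp(x)
        if rng == 0:
            raise ValueError("constant series: min-max normalization undefined")
        return (x - x.min()) / rng
    raise ValueError(f"unknown normalization {scheme!r}; use one of {VALID_NORMALIZATIONS}")


@dataclass
class GreyRelationalResult:
    """Grey relational degrees per comparison series (and per group)."""

    rho: float
    normalization: str
    #: index = comparison name; columns = group labels (+ "overall" when grouped)
    degrees: pd.Series | pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        if isinstance(self.degrees, pd.Series):
            return self.degrees.rename("degree").to_frame()
        return self.degrees


def grey_relational(reference, comparisons: dict, rho: float = 0.5,
                    normalization: str = "mean") -> GreyRelationalResult:
    """Deng's grey relational degree of each comparison vs. the reference.

    Parameters
    ----------
    reference : 1-D sequence
    comparisons : mapping name → 1-D sequence of the same length
    rho : resolution coefficient in (0, 1]
    normalization : "mean" (divide by series mean), "initial" (divide by
        first value) or "minmax".
    """
    if not (0 < rho <= 1):
        raise ValueError(f"resolution coefficient must be in (0, 1], got {rho}")
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 1 or ref.size < 2:
        raise ValueError("reference must be a 1-D series of length ≥ 2")
    if not comparisons:
        raise ValueError("need at least one comparison series")

    ref_n = _normalize(ref, normalization)
    names = list(comparisons)
    deltas = np.empty((len(names), ref.size))
    for i, name in enumerate(names):
        comp = np.asarray(comparisons[name], dtype=float)
        if comp.shape != ref.shape:
            raise ValueError(f"comparison {name!r} length {comp.size} != reference {ref.size}")
        deltas[i] = np.abs(ref_n - _normalize(comp, normalization))

    dmin, dmax = deltas.min(), deltas.max()
    if dmax == 0.0:  # all series identical after normalization
        degrees = pd.Series(1.0, index=names)
    else:
        xi = (dmin + rho * dmax) / (deltas + rho * dmax)
        degrees = pd.Series(xi.mean(axis=1), index=names)
    return GreyRelationalResult(rho=rho, normalization=normalization, degrees=degrees)


def grey_relational_table(panel: pd.DataFrame, incidence: pd.DataFrame,
                          rho: float = 0.5, normalization: str = "mean") -> GreyRelationalResult:
    """Year-grouped grey relational degrees of each lag column vs. incidence.

    For each outcome year the reference is the cross-region incidence and
    the comparisons are the lag columns restricted to that year; an
    additional "overall" column pools all region-years. Mirrors the
    per-year + overall layout conventional for annual registry panels.
    """
    data = align(panel, incidence)
    cols = {}
    for year, grp in data.groupby("year", sort=True):
        res = grey_relational(grp["incidence"], {c: grp[c] for c in LAG_COLUMNS},
                              rho=rho, normalization=normalization)
        cols[str(year)] = res.degrees
    overall = grey_relational(data["incidence"], {c: data[c] for c in LAG_COLUMNS},
                              rho=rho, normalization=normalization)
    cols["overall"] = overall.degrees
    table = pd.DataFrame(cols)
    table.index.name = "lag"
    return GreyRelationalResult(rho=rho, normalization=normalization, degrees=table)
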