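"""Region-year exposure panels and incidence series.

The canonical in-memory containers are plain pandas DataFrames:

* an *exposure panel* has columns ``region_id, year, lag0..lag9`` where
  ``lagL`` is the annual-mean exposure (μg/m³) L calendar years before
  ``year`` (lag0 = the outcome year itself);
* an *incidence series* has columns ``region_id, year, incidence`` with
  incidence in cases per 100,000 person-years.

This module holds the shared validation, alignment and CSV I/O used by
every analysis stage.
"""

from __future__ import annotations

import pandas as pd

N_LAGS = 10
LAG_COLUMNS = [f"lag{i}" for i in range(N_LAGS)]
KEY_COLUMNS = ["region_id", "year"]


class PanelError(ValueError):
    """Raised when a panel or incidence series violates its contract."""


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check an exposure panel's invariants and return it unchanged.

    Raises :class:`PanelError` naming the offending column or rows when a
    lag column is missing, keys are duplicated, or exposures are missing,
    non-finite or non-positive.
    """
    missing = [c for c in KEY_COLUMNS + LAG_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelError(f"panel is missing required column(s): {', '.join(missing)}")
    dup = panel.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        rows = panel.loc[dup, KEY_COLUMNS].head(3).to_records(index=False).tolist()
        raise PanelError(f"duplicate (region_id, year) keys, e.g. {rows}")
    lags = panel[LAG_COLUMNS]
    if lags.isna().any().any():
        bad = lags.columns[lags.isna().any()].tolist()
        raise PanelError(f"missing exposure values in column(s): {', '.join(bad)}")
    import numpy as np

    vals = lags.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise PanelError("non-finite exposure values in panel")
    if (vals <= 0).any():
        raise PanelError("exposures must be strictly positive (μg/m³)")
    return panel


def validate_incidence(incidence: pd.DataFrame) -> pd.DataFrame:
    """Check an incidence series' invariants and return it unchanged."""
    missing = [c for c in KEY_COLUMNS + ["incidence"] if c not in incidence.columns]
    if missing:
        raise PanelError(f"incidence is missing required column(s): {', '.join(missing)}")
    if incidence.duplicated(subset=KEY_COLUMNS).any():
        raise PanelError("duplicate (region_id, year) keys in incidence series")
    vals = incidence["incidence"]
    if vals.isna().any() or (vals < 0).any():
        raise PanelError("incidence must be present and ≥ 0 (cases per 100,000)")
    return incidence


def align(panel: pd.DataFrame, incidence: pd.DataFrame) -> pd.DataFrame:
    """Inner-join a validated panel with its incidence series on (region, year).

    Raises :class:`PanelError` if the key sets do not match exactly; the
    analysis stages all require one incidence per panel row.
    """
    validate_panel(panel)
    validate_incidence(incidence)
    pk = set(map(tuple, panel[KEY_COLUMNS].itertuples(index=False)))
    ik = set(map(tuple, incidence[KEY_COLUMNS].itertuples(index=False)))
    if pk != ik:
        raise PanelError(
            f"panel and incidence keys differ: {len(pk - ik)} panel-only, "
            f"{len(ik - pk)} incidence-only"
        )
    merged = panel.merge(incidence[KEY_COLUMNS + ["incidence"]], on=KEY_COLUMNS)
    return merged.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)


def read_dataset(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a combined ``region_id, year, lag0..lag9, incidence`` CSV.

    Returns the (panel, incidence) pair, both validated.
    """
    df = pd.read_csv(path)
    missing = [c for c in KEY_COLUMNS + LAG_COLUMNS + ["incidence"] if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing required column(s): {', '.join(missing)}")
    panel = validate_panel(df[KEY_COLUMNS + LAG_COLUMNS].copy())
    incidence = validate_incidence(df[KEY_COLUMNS + ["incidence"]].copy())
    return panel, incidence


def write_dataset(panel: pd.DataFrame, incidence: pd.DataFrame, path) -> None:
    """Write panel + incidence as one combined CSV."""
    align(panel, incidence).to_csv(path, index=False)
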