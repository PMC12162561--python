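import numpy as np
import pandas as pd
import pytest

from lagrisk import SynthConfig, generate_dataset, generate_panel
from lagrisk.panel import LAG_COLUMNS


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset (30 regions × 5 years, ar_rho 0.95)."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_panel(default_dataset):
    return default_dataset[0]


@pytest.fixture(scope="session")
def default_incidence(default_dataset):
    return default_dataset[1]


@pytest.fixture(scope="session")
def wide_panel():
    """200-region panel used for oracle comparisons."""
    panel, _ = generate_panel(SynthConfig(n_regions=200, n_years=1, seed=42))
    return panel


def make_incidence(panel: pd.DataFrame, values) -> pd.DataFrame:
    """Incidence series aligned to a panel with explicit values."""
    return pd.DataFrame(
        {
            "region_id": panel["region_id"],
            "year": panel["year"],
            "incidence": np.asarray(values, dtype=float),
        }
    )


@pytest.fixture
def linear_lag0_incidence(default_panel):
    """Incidence exactly linear in lag0 (noise-free)."""
    return make_incidence(default_panel, 10.0 + 0.5 * default_panel["lag0"])


LAGS = LAG_COLUMNS
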