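from datetime import date

import numpy as np
import pandas as pd
import pytest

from stackcast.features import LagSpec, prepare_datasets
from stackcast.synthetic import GeneratorConfig, default_holidays, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default-configuration panel (1461 days, seed 42)."""
    return generate_panel(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_panel():
    """A short panel for cheap structural tests (one year plus change)."""
    return generate_panel(GeneratorConfig(n_days=400, seed=7))


@pytest.fixture(scope="session")
def small_split(small_panel):
    holidays = default_holidays(range(2015, 2017), seed=0)
    return prepare_datasets(small_panel, LagSpec(6), holidays, date(2015, 11, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_design(rng):
    """A 60-row full-rank design with a known linear signal."""
    idx = pd.date_range("2015-01-01", periods=60, freq="D")
    X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"], index=idx)
    y = pd.Series(X.to_numpy() @ [2.0, -1.0, 0.5] + 30.0
                  + 0.1 * rng.normal(size=60), index=idx, name="y")
    return X, y
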