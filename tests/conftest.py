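import numpy as np
import pandas as pd
import pytest

from geoexpose.scenario import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Small but structurally complete scenario for fast tests."""
    return ScenarioConfig(
        grid_nx=15, grid_ny=15, n_units=40, n_municipalities=25,
        n_stations=20, n_polluted_sites=8, soil_spacing_cells=2,
        mean_obs_per_unit=10, seed=42,
    )


@pytest.fixture
def tiny_panel():
    """Hand-built censored panel: two substances, three units."""
    rows = []
    for u, d, s, v, c in [
        ("U1", "2004-03-01", "S0", 2.0, False),
        ("U1", "2004-03-01", "S1", 2.2, False),
        ("U1", "2007-06-01", "S0", 0.5, True),
        ("U1", "2007-06-01", "S1", 1.4, False),
        ("U2", "2005-01-15", "S0", 3.0, False),
        ("U2", "2005-01-15", "S1", 3.1, False),
        ("U3", "2010-09-30", "S0", 0.5, True),
        ("U3", "2010-09-30", "S1", 0.5, True),
    ]:
        rows.append({"unit_id": u, "date": d, "substance": s,
                     "value": 0.5 if c else v, "censored": c, "dl": 0.5})
    return pd.DataFrame(rows)
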