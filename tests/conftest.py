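import numpy as np
import pandas as pd
import pytest

from temposelect.synthetic_data import (
    HarmonicBeta,
    TrueBetaSpec,
    make_landscape,
    make_synthetic_pairs,
)


@pytest.fixture(scope="session")
def landscape():
    return make_landscape(seed=11, n_rows=100, n_cols=100, cell_size=10.0)


@pytest.fixture(scope="session")
def harmonic_spec():
    """Two-signal truth: seasonal deciduous forest, diel arable land."""
    return TrueBetaSpec(
        {
            "deciduous_forest": HarmonicBeta(a0=0.3, a_year=1.0),
            "arable": HarmonicBeta(a0=-0.3, a_hour=1.0),
        }
    )


@pytest.fixture(scope="session")
def small_pairs(harmonic_spec):
    """A light pairs table covering every temporal cell (40 pairs/cell)."""
    return make_synthetic_pairs(seed=5, beta_spec=harmonic_spec, n_pairs_per_cell=40)


def hourly_track(n: int, individual: str = "a", start: str = "2016-03-01T00:00:00Z"):
    """Helper: straight-line hourly fixes, 100 m apart."""
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "id": individual,
            "timestamp": [t0 + pd.Timedelta(hours=i) for i in range(n)],
            "x": 100.0 * np.arange(n),
            "y": np.zeros(n),
        }
    )
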