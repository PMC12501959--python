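import numpy as np
import pandas as pd
import pytest

from camtrap_cooccur import synthetic_data as sd


def make_stations(n=3, survey_days=30, start="2022-06-01"):
    """Minimal hand-built station table for unit tests."""
    start = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "station_id": [f"S{i}" for i in range(1, n + 1)],
            "x": np.arange(n) * 500.0,
            "y": np.zeros(n),
            "deploy_start": [start] * n,
            "deploy_end": [start + pd.Timedelta(days=survey_days)] * n,
        }
    ).set_index("station_id", drop=False)


def make_events(rows):
    """rows: iterable of (station_id, species, timestamp-string)."""
    return pd.DataFrame(
        {
            "station_id": [r[0] for r in rows],
            "species": [r[1] for r in rows],
            "timestamp": pd.to_datetime([r[2] for r in rows]),
        }
    )


@pytest.fixture(scope="session")
def small_survey():
    """One simulated survey, shared across tests that only read it."""
    cfg = sd.SimConfig(n_stations=20, n_transects=5, survey_days=120, seed=7)
    stations, z, events = sd.simulate_survey(cfg)
    return cfg, stations, z, events
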