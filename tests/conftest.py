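import numpy as np
import pandas as pd
import pytest

from bvitals import SimulationConfig, simulate_cohort, simulate_daily_features


def make_events(rows):
    """Build an events frame from (stream, start, end, payload-dict) tuples."""
    recs = []
    for stream, start, end, payload in rows:
        rec = {
            "participant_id": payload.pop("participant_id", 1),
            "stream": stream,
            "start": pd.Timestamp(start),
            "end": pd.Timestamp(end),
            "cluster_id": np.nan,
            "dist_home_m": np.nan,
            "steps": np.nan,
            "cadence_steps_per_s": np.nan,
            "display_on": None,
            "bout": None,
        }
        rec.update(payload)
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def events_factory():
    return make_events


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_participants=6, seed=123)


@pytest.fixture(scope="session")
def small_traits(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def one_participant_days(small_config, small_traits):
    return simulate_daily_features(small_traits.iloc[0], 14, 123, small_config)
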