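from datetime import datetime

import pandas as pd
import pytest

from feedercalls import aggregation, synthetic


def make_visits(rows):
    """Visit frame from (site, iso_timestamp, tag, species) tuples."""
    return pd.DataFrame(
        [(s, pd.Timestamp(t), tag, sp) for s, t, tag, sp in rows],
        columns=["site_id", "timestamp", "tag_id", "species"],
    )


def make_calls(rows):
    """Call frame from (site, iso_timestamp, call_type, n_notes) tuples."""
    return pd.DataFrame(
        [(s, pd.Timestamp(t), ct, n) for s, t, ct, n in rows],
        columns=["site_id", "timestamp", "call_type", "n_notes"],
    )


@pytest.fixture(scope="session")
def playback_experiment():
    """One seeded 12-site playback experiment at default effects."""
    trials, visits_by_trial = synthetic.simulate_playback_experiment(12, seed=42)
    return trials, visits_by_trial


@pytest.fixture(scope="session")
def playback_records_df(playback_experiment):
    trials, visits_by_trial = playback_experiment
    return aggregation.playback_records(trials, visits_by_trial)


@pytest.fixture(scope="session")
def discovery_hourly():
    """Hourly table from a seeded 18-trial discovery experiment."""
    visits, calls = synthetic.simulate_discovery_experiment(18, seed=7)
    return aggregation.hourly_table(visits, calls)


TRIAL_START = datetime(2017, 2, 10, 8, 30)
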