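import numpy as np
import pandas as pd
import pytest

from crowflock import synthetic


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study reused across read-only tests."""
    world = synthetic.WorldConfig(monitoring_stride=4)
    agents = synthetic.AgentConfig(n_marked=160, n_unmarked=300)
    return synthetic.simulate_study(world, agents, seed=7)


@pytest.fixture(scope="session")
def small_records(small_study):
    return small_study["records"]


def make_records(rows):
    """Build a sightings frame from (date, session, bird_id, marked) tuples
    or full dicts."""
    out = []
    for i, r in enumerate(rows):
        if isinstance(r, dict):
            d = dict(r)
        else:
            d = dict(zip(("date", "session", "bird_id", "marked"), r))
        d.setdefault("age_class", "nonjuvenile")
        d.setdefault("flying", 0)
        d.setdefault("x_m", float(10 * i))
        d.setdefault("y_m", 0.0)
        d.setdefault("zone_id", "Z0")
        out.append(d)
    df = pd.DataFrame(out)
    df["date"] = pd.to_datetime(df["date"])
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(0)
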