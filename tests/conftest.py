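import numpy as np
import pandas as pd
import pytest

from fintrack.pipeline import make_fixtures
from fintrack.synthetic import SimConfig, generate_env_world


@pytest.fixture(scope="session")
def fixture_data():
    """Miniature deterministic 2-individual, 6-hour dataset."""
    return make_fixtures(seed=3)


@pytest.fixture(scope="session")
def small_world():
    cfg = SimConfig(seed=5, n_individuals=1, duration_h=12.0)
    return generate_env_world(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def fix_frame(times_s, xs, ys, ind=0, t0="2020-01-01"):
    """Helper: build a fix table from seconds offsets and coordinates."""
    t0 = pd.Timestamp(t0)
    return pd.DataFrame({
        "id": ind,
        "time": [t0 + pd.Timedelta(seconds=float(s)) for s in times_s],
        "x": np.asarray(xs, float),
        "y": np.asarray(ys, float),
    })


def depth_frame(depths, ind=0, t0="2020-01-01"):
    """Helper: 1 Hz depth table from a sequence of depths."""
    t0 = pd.Timestamp(t0)
    return pd.DataFrame({
        "id": ind,
        "time": t0 + pd.to_timedelta(np.arange(len(depths)), "s"),
        "depth": np.asarray(depths, float),
    })
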