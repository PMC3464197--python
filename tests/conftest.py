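import numpy as np
import pytest
from hypothesis import settings

from flysleep.dam_io import ChannelSeries
from flysleep.synthetic import PRESETS, simulate_cohort

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_series(counts, start_zt=0, missing=None, **kw):
    """Shorthand ChannelSeries for hand-built fixtures."""
    kw.setdefault("fly_id", "test")
    return ChannelSeries(counts=np.asarray(counts, dtype=np.int64),
                         start_zt=start_zt, missing=missing, **kw)


@pytest.fixture(scope="session")
def wt_cohort():
    """Frozen wild-type-like baseline cohort (n=50, 5 days, seed 1)."""
    return simulate_cohort(PRESETS["wt"], 50, 5, seed=1)


@pytest.fixture(scope="session")
def inc_cohort():
    """Frozen short-sleeper cohort (n=50, 5 days, seed 1)."""
    return simulate_cohort(PRESETS["inc_like"], 50, 5, seed=1)
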