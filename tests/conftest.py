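import numpy as np
import pandas as pd
import pytest

from rumblekit import synth
from rumblekit.trace import Trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_trace():
    """Unit-amplitude 30 Hz tone, 20 s at 200 Hz, vertical channel."""
    fs = 200.0
    t = np.arange(int(20 * fs)) / fs
    return Trace(np.sin(2 * np.pi * 30.0 * t), fs, channel="Z")


@pytest.fixture
def night_clock():
    return synth.hour_of_day_clock(pd.Timestamp("2024-08-02 00:00:00"))


@pytest.fixture
def day_clock():
    return synth.hour_of_day_clock(pd.Timestamp("2024-08-02 10:00:00"))


@pytest.fixture(scope="session")
def small_scene():
    """A 10-minute night scene with a handful of injected sources."""
    cfg = synth.SceneConfig(duration=600.0, seed=7, rumble_rate=30.0)
    return synth.render_scene(cfg)
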