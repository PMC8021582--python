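import numpy as np
import pytest
from hypothesis import settings

from ictaldetect import ChannelSeries

# property tests must replay identically run-to-run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def sinusoid_channel():
    """Clean 4 Hz unit sinusoid, 60 s at 128 Hz."""
    fs = 128.0
    t = np.arange(int(fs * 60)) / fs
    return ChannelSeries(np.sin(2 * np.pi * 4 * t), fs=fs,
                         patient_id="sim", channel_id="c0")


@pytest.fixture(scope="session")
def emu_sweep():
    """The default synthetic benchmark run over ten seeds (shared)."""
    from ictaldetect.pipeline import run_benchmark

    return [run_benchmark(seed=s) for s in range(10)]


@pytest.fixture(scope="session")
def drift_sweep():
    """The drifting-noise-floor benchmark (subtle events) over ten seeds."""
    from ictaldetect.pipeline import run_drift_benchmark

    return [run_drift_benchmark(seed=s) for s in range(10)]
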