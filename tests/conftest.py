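import numpy as np
import pytest

from rehabconn.connectivity import AnalyticEpoch, get_band
from rehabconn.preprocessing import EpochedEEG
from rehabconn.synthetic import synthetic_montage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epoched(data, fs=500.0, t0_ms=-100.0, **meta) -> EpochedEEG:
    """EpochedEEG around an array, with a synthetic unit-sphere montage."""
    data = np.asarray(data, dtype=float)
    names, pos = synthetic_montage(data.shape[1])
    return EpochedEEG(data=data, t0_offset_ms=t0_ms, sampling_rate=fs,
                      channel_names=names, channel_positions=pos, **meta)


def make_analytic(x, band="theta", fs=500.0) -> AnalyticEpoch:
    """AnalyticEpoch directly from complex samples (bypasses filtering)."""
    return AnalyticEpoch(x=np.asarray(x, dtype=complex), band=get_band(band),
                         sampling_rate=fs)


@pytest.fixture(scope="session")
def tone_pair():
    """Two 6 Hz analytic tones with a constant 90 degree lag, noiseless."""
    fs, n = 500.0, 1000
    t = np.arange(n) / fs
    x1 = np.exp(1j * 2 * np.pi * 6 * t)
    x2 = np.exp(1j * (2 * np.pi * 6 * t - np.pi / 2))
    return make_analytic(np.stack([x1, x2]))
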