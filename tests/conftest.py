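import numpy as np
import pytest

from fnirslab import Recording, make_channels


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def hb_recording(data_hbo, data_hbr, fs=10.0, **kw):
    """Two-chromophore recording from explicit HbO/HbR blocks."""
    data_hbo = np.atleast_2d(np.asarray(data_hbo, dtype=float))
    if data_hbo.shape[0] == 1:
        data_hbo = data_hbo.T
    data_hbr = np.atleast_2d(np.asarray(data_hbr, dtype=float))
    if data_hbr.shape[0] == 1:
        data_hbr = data_hbr.T
    n_ch = data_hbo.shape[1]
    return Recording(
        data=np.hstack([data_hbo, data_hbr]), fs=fs, signal_kind="hb",
        channels=make_channels(n_ch), chromophores=("HbO", "HbR"), **kw)


@pytest.fixture
def sinusoid_recording():
    """Four channels of distinct on-bin sinusoids, 200 s at 10 Hz."""
    fs, n = 10.0, 2000
    t = np.arange(n) / fs
    hbo = np.column_stack([
        2.0 * np.cos(2 * np.pi * 0.05 * t),
        1.0 * np.cos(2 * np.pi * 0.02 * t),
        0.5 * np.cos(2 * np.pi * 0.10 * t),
        3.0 * np.cos(2 * np.pi * 0.05 * t + 1.0),
    ])
    return hb_recording(hbo, -hbo / 3.0, fs=fs)
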