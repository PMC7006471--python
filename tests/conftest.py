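import numpy as np
import pytest

import nfpredict as nf


@pytest.fixture(scope="session")
def band_set():
    return nf.build_frequency_bands(8, 30, 3, 1)


@pytest.fixture(scope="session")
def short_recording():
    """A 40 s two-channel recording: 10 Hz sinusoid on ch0, silence on ch1."""
    srate = 128.0
    t = np.arange(int(40 * srate)) / srate
    data = np.vstack([np.sin(2 * np.pi * 10.0 * t), np.zeros_like(t)])
    return nf.EEGRecording(data=data, srate=srate, channel_names=["C3", "Cz"])


@pytest.fixture(scope="session")
def small_sim():
    """A short synthetic session: 2 blocks (80 s), reduced montage."""
    return nf.SimulationConfig(n_blocks=2, seed=42, srate=128.0)


@pytest.fixture(scope="session")
def small_design(small_sim, band_set):
    rec = nf.simulate_eeg(small_sim)
    x0 = nf.sliding_band_power(rec, band_set)
    return nf.assemble_design(x0, mode="full")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
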