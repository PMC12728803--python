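import numpy as np
import pytest

import lfpclean as L


@pytest.fixture(scope="session")
def mt_params():
    """Working spectral configuration: 2 s windows, 50% overlap, W = 1 Hz."""
    return L.SpectralParams.from_duration(250.0, 2.0, half_bandwidth=1.0)


@pytest.fixture(scope="session")
def welch_params():
    return L.SpectralParams(250.0, 500, method="hanning_welch")


@pytest.fixture(scope="session")
def default_recording():
    """One default 60 s two-channel synthetic recording with its ground truth."""
    spec = L.SimulationSpec(duration=60.0, seed=42)
    return L.assemble_recording(spec)


def make_spectrogram(db_matrix, df=0.5):
    """Build a Spectrogram directly from a (n_windows, n_freqs) dB matrix."""
    db_matrix = np.asarray(db_matrix, dtype=float)
    n_freq = db_matrix.shape[1]
    nfft = 2 * (n_freq - 1)
    fs = df * nfft  # so the bin spacing equals df
    params = L.SpectralParams(fs, nfft, nfft=nfft, half_bandwidth=1.0)
    freqs = np.arange(n_freq) * df
    windows = [L.Psd(freqs, 10.0 ** (row / 10.0), params) for row in db_matrix]
    starts = list(range(0, n_freq * len(windows), nfft // 2))[: len(windows)]
    return L.Spectrogram(windows, starts, params)
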