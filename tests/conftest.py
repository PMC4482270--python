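import numpy as np
import pytest
from scipy import signal

from eegbm.preprocess import Recording
from eegbm.channels import TEN_TWENTY_LABELS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def filtered_noise_epochs(rng, n_epochs, fs=200.0, n_channels=18):
    """Independent Gaussian derivations conditioned like the network path:
    0.5-50 Hz zero-phase band-pass, demeaned, unit variance per epoch."""
    n = int(2 * fs)
    sos = signal.butter(3, [0.5, 50.0], btype="bandpass", fs=fs, output="sos")
    out = np.empty((n_epochs, n, n_channels))
    for e in range(n_epochs):
        x = rng.standard_normal((n + 200, n_channels))
        x = signal.sosfiltfilt(sos, x, axis=0)[100:100 + n]
        x = x - x.mean(axis=0)
        out[e] = x / x.std(axis=0)
    return out


@pytest.fixture
def noise_recording(rng):
    """A 120 s, 200 Hz recording of independent channel noise."""
    fs = 200.0
    samples = rng.standard_normal((int(120 * fs), 19)) * 10.0
    return Recording(
        subject_id="noise", fs=fs, samples=samples,
        channel_labels=TEN_TWENTY_LABELS,
    )
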