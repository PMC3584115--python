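import numpy as np
import pytest

from gate50 import (
    ClickProtocol,
    SubjectTruth,
    load_published_model,
    measure_pair,
    preprocess,
    synthesize_eeg,
)


@pytest.fixture(scope="session")
def published():
    return load_published_model()


@pytest.fixture(scope="session")
def clean_recording():
    """Noise-free session: S1 2.0 uV / S2 1.0 uV at 60 ms, 120 pairs."""
    truth = SubjectTruth(
        group="control", true_s1_amp=2.0, true_s2_amp=1.0,
        true_s1_latency=60.0, noise_sd=0.0, blink_rate=0.0, artifact_rate=0.0,
    )
    return synthesize_eeg(truth, ClickProtocol(n_pairs=120), seed=101)


@pytest.fixture(scope="session")
def clean_result(clean_recording):
    erp, epochs = preprocess(clean_recording)
    return measure_pair(erp, 0.0, 500.0), erp, epochs


def synthetic_erp(segments, window=(-100, 923), fs=1000.0):
    """Build an ERPAverage whose samples are zero except at listed
    (time_ms, value) points — a direct way to construct peak/trough cases."""
    from gate50 import ERPAverage

    n = window[1] - window[0] + 1
    wave = np.zeros(n)
    for t_ms, value in segments:
        wave[int(t_ms - window[0])] = value
    return ERPAverage(wave, window, fs, 1)
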