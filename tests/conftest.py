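import warnings

import numpy as np
import pytest

from mvapred import MinuteSegment, SynthSpec, synth_ecg_record


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # segment-drop / detector warnings are part of normal operation
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def clean_minute():
    """Jitter-free 60-bpm minute at 250 Hz with ground truth."""
    rec, truth = synth_ecg_record(SynthSpec(
        fs=250.0, duration_s=62.0, mean_rr=1.0, rr_jitter_sd=0.0,
        qrs_width_ms=90.0, noise_sd=0.0, seed=7, drift=None,
    ))
    seg = MinuteSegment("clean", 0, rec.samples[: 250 * 60], 250.0)
    return seg, truth


@pytest.fixture(scope="session")
def jittered_minute():
    rec, truth = synth_ecg_record(SynthSpec(
        fs=250.0, duration_s=62.0, mean_rr=0.8, rr_jitter_sd=0.04,
        noise_sd=0.01, seed=11, drift=None,
    ))
    seg = MinuteSegment("jitter", 0, rec.samples[: 250 * 60], 250.0)
    return seg, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
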