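import numpy as np
import pytest

from fdeeg import EvokedTemplate, TimeSeries, TrialSpec, make_session


@pytest.fixture(scope="session")
def white_noise_8192():
    """20 independent white-noise records of length 8192, fixed seeds."""
    return [np.random.default_rng(s).standard_normal(8192) for s in range(1, 21)]


@pytest.fixture
def evoked_fixture_1khz():
    """Quiet-background trial at 1 kHz with a +9 μV peak at 118 ms and a
    −4.97 μV rebound at 170 ms post-stimulus."""
    rate = 1000.0
    n = 2000
    t = np.arange(n) / rate
    template = EvokedTemplate(
        p_latency=0.118, p_amplitude=9.0, n_latency=0.170, n_amplitude=-4.97,
        width=0.012,
    )
    vals = np.zeros(n)
    post = t >= 1.0
    vals[post] = template.waveform(t[post] - 1.0)
    return TimeSeries(vals, rate, 0.0, stimulus_onset=1.0)


@pytest.fixture(scope="session")
def evoked_session():
    """40 seeded evoked trials on 2 μV fGn background (default spec)."""
    return make_session(TrialSpec(seed=2024), 40, subject_label="synthetic")


# Table of per-subject evoked-response features (initiation ms, duration s,
# peak-to-peak μV), real and predicted columns, used for the averaging
# arithmetic checks.
SUBJECT_FEATURE_TABLE = {
    "real": {
        "initiation_ms": [118, 120, 110, 100, 112, 120],
        "duration_s": [0.052, 0.054, 0.058, 0.078, 0.043, 0.050],
        "peak_to_peak_uV": [13.97, 12.86, 15.24, 16.28, 12.50, 13.85],
    },
    "predicted": {
        "initiation_ms": [127, 120, 120, 120, 121, 130],
        "duration_s": [0.047, 0.067, 0.060, 0.057, 0.041, 0.044],
        "peak_to_peak_uV": [13.07, 13.75, 15.24, 15.50, 11.81, 15.50],
    },
}

PRINTED_AVERAGES = {
    "real": {"initiation_ms": 113, "duration_s": 0.055, "peak_to_peak_uV": 14.11},
    "predicted": {"initiation_ms": 123, "duration_s": 0.052, "peak_to_peak_uV": 14.14},
}
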