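import numpy as np
import pytest

from hivesignals import (
    BandConfig,
    DetectionParams,
    amplitude_for_snr,
    generate_recording,
    random_schedule,
)

# All synthetic fixtures use a 4410 Hz sample rate: every signal component
# (max 3*400 Hz stop-signal harmonic) sits below the 2205 Hz Nyquist, and
# the spectro-temporal structure of the bands is unchanged relative to the
# field hardware's 44.1 kHz.
FS = 4410.0


@pytest.fixture(scope="session")
def cfg() -> BandConfig:
    return BandConfig(sample_rate=FS)


@pytest.fixture(scope="session")
def params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture(scope="session")
def clean_recording(cfg):
    """A 5-min, 2-channel recording at 20 dB SNR with its ground truth."""
    rates = {"waggle_run": 60.0, "fanning": 24.0, "stop_signal": 48.0}
    amp = amplitude_for_snr(20.0, 1.0)
    schedule = random_schedule(rates, 300.0, 2, seed=11, band_config=cfg, amplitude=amp)
    recording, truth = generate_recording(
        schedule, 300.0, 2, noise_sigma=1.0, seed=11, band_config=cfg
    )
    return recording, truth, schedule
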