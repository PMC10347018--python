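import numpy as np
import pytest

from pcg_lstf.preprocessing import Envelope, PeakList
from pcg_lstf.synthetic_pcg import SyntheticSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_recording():
    """A 20 s normal recording at 75 bpm with mild noise, plus ground truth."""
    spec = SyntheticSpec(duration_s=20.0, heart_rate_bpm=75.0,
                         systole_ms=300.0, jitter_ms=5.0, snr_db=25.0,
                         seed=7)
    return generate_recording(spec)


def peaks_ms(times, amps, threshold=0.3):
    """Shorthand PeakList constructor used across preprocessing tests."""
    return PeakList(np.asarray(times, float), np.asarray(amps, float),
                    threshold)


def envelope_1ms(values):
    """Envelope on a 1 ms grid (rate 1000 Hz, no frame offset)."""
    return Envelope(np.asarray(values, float), rate_hz=1000.0, t0_ms=0.0)
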