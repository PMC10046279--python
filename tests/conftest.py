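import numpy as np
import pytest

from ecgqc.segment import ECGSegment
from ecgqc.synth import SegmentSpec, generate_segment


@pytest.fixture(scope="session")
def clean_segment() -> ECGSegment:
    """Contamination-free 60 bpm segment: 20 beats over 20 s."""
    return generate_segment(SegmentSpec(heart_rate_bpm=60, seed=1))


@pytest.fixture(scope="session")
def noisy_segment() -> ECGSegment:
    """Same heart as clean_segment drowned in broadband noise."""
    return generate_segment(SegmentSpec(heart_rate_bpm=60, noise_sigma_mv=0.6, seed=1))


def make_segment(values, fs_hz=250, **kw) -> ECGSegment:
    return ECGSegment(values=np.asarray(values, dtype=float), fs_hz=fs_hz, **kw)
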