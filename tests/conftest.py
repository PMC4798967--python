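import numpy as np
import pytest

from neurotact.mnt_encoder import EncoderParams, encode_trial
from neurotact.spike_coding import compute_metrics, segment_bursts
from neurotact.synthetic_touch import (
    SlidingProtocol,
    StimulusPair,
    noise_free,
    synth_sensor_trace,
)

STANDARD_SPS = (0.5, 1.0, 1.5, 2.0, 3.0)


def encode_single_sp(sp: float, seed: int = 0, calib=None):
    """Encode a trial whose both halves carry the same spatial period and
    return the first-half slide-window spike train."""
    pair = StimulusPair(label="test", order="+", first_sp=sp, second_sp=sp)
    trace = synth_sensor_trace(pair, SlidingProtocol(), calib or noise_free(), seed=seed)
    first, _, _ = encode_trial(trace, EncoderParams())
    return first


@pytest.fixture(scope="session")
def noisefree_trains():
    """Noise-free slide-window spike trains for every standard SP."""
    return {sp: encode_single_sp(sp) for sp in STANDARD_SPS}


@pytest.fixture(scope="session")
def noisefree_metrics(noisefree_trains):
    return {
        sp: compute_metrics(train, slide_duration=2.0, grating=sp, velocity=10.0)
        for sp, train in noisefree_trains.items()
    }


@pytest.fixture(scope="session")
def noisefree_bursts(noisefree_trains):
    return {sp: segment_bursts(train) for sp, train in noisefree_trains.items()}
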