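import numpy as np
import pytest

from blinkhazard import protocol as proto
from blinkhazard import synth_eog
from blinkhazard.spectral import EpochSet


@pytest.fixture(scope="session")
def full_protocol():
    """The full study design: 240 sequences, 60 targets, 750-ms SOA."""
    return proto.generate_protocol(240, 60, 750.0, seed=11)


@pytest.fixture(scope="session")
def small_protocol():
    return proto.generate_protocol(60, 15, 750.0, seed=5)


@pytest.fixture(scope="session")
def default_recording(small_protocol):
    """A ~3.75-min synthetic recording with default noise, plus its
    ground-truth log."""
    model = synth_eog.TimingModel(seed=21)
    times = synth_eog.sample_blink_times(model, small_protocol)
    rec, log = synth_eog.render_recording(
        times, duration_ms=small_protocol.duration_ms,
        rng=np.random.default_rng(22))
    return rec, log


def epochs_from_latencies(latencies, participant_id="p"):
    """Minimal single-epoch EpochSet wrapper for histogram-level tests."""
    lat = np.asarray(latencies, dtype=float)
    return EpochSet(participant_id=participant_id,
                    epoch_onsets_ms=np.array([0.0]),
                    latencies_ms=[lat])
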