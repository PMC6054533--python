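import numpy as np
import pytest

from behavrc.behavior_core import BehaviorTrack
from behavrc.stimgen import DEFAULT_DT, NoiseParams, generate_noise


@pytest.fixture(scope="session")
def noise_stim():
    """Five minutes of default correlated noise, fixed seed."""
    return generate_noise(NoiseParams(seed=3, duration=300.0))


@pytest.fixture(scope="session")
def noise_params():
    return NoiseParams(seed=3, duration=300.0)


def make_track(labels, track_id="t0", t_start=0.0, dt=DEFAULT_DT):
    """Build a track from a list of (label, n_frames) runs or raw labels."""
    if labels and isinstance(labels[0], tuple):
        seq = []
        for lab, n in labels:
            seq.extend([lab] * n)
        labels = seq
    return BehaviorTrack(track_id=track_id, t_start=t_start, dt=dt,
                         labels=np.asarray(labels, dtype=object))
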