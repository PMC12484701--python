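"""Shared fixtures and independent oracles."""
import math

import numpy as np
import pytest

from seegkit.io import ChannelInfo, RecordingSession


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


def make_session(
    n_channels=4,
    fs=2048.0,
    duration_s=10.0,
    shaft="A",
    roi="Amy",
    events=(),
    data=None,
    seed=0,
):
    """Small monopolar session with one shaft."""
    n = int(round(fs * duration_s))
    if data is None:
        data = np.random.default_rng(seed).standard_normal((n_channels, n))
    channels = [
        ChannelInfo(label=f"{shaft}{k + 1}", shaft_id=shaft, contact_index=k + 1, roi=roi)
        for k in range(data.shape[0])
    ]
    return RecordingSession(data=data, fs=fs, channels=channels, events=list(events))


def plv_bruteforce(phase_a, phase_b):
    """Independent PLV oracle: scalar trig accumulation over the phase
    difference series (no vectorized complex arithmetic)."""
    c = s = 0.0
    for x, y in zip(phase_a.tolist(), phase_b.tolist()):
        d = x - y
        c += math.cos(d)
        s += math.sin(d)
    return math.hypot(c, s) / len(phase_a)
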