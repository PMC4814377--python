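import numpy as np
import pytest

from flashtrace.photometry import IntensityTrace


def make_trace(values, frame_rate=30.0, t0=0.0, track_id=0):
    """IntensityTrace from a bare value array, for signal-level tests."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    return IntensityTrace(
        track_id=track_id,
        times=t0 + np.arange(n) / frame_rate,
        values=values,
        background=np.zeros(n),
        frame_rate=frame_rate,
        frames=np.arange(n),
        is_gap=np.zeros(n, dtype=bool),
    )


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
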