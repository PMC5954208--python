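import numpy as np
import pytest

from varietywalk.io import Session, StepEvent


def make_session(points, times=None, session_id="s", room=(6.0, 9.0), **kw):
    """Session from a list of (x, y) points; default 0.3 s cadence."""
    if times is None:
        times = [0.3 * i for i in range(len(points))]
    steps = [StepEvent(t=t, x=x, y=y) for t, (x, y) in zip(times, points)]
    return Session(
        session_id=session_id,
        steps=steps,
        room_width=room[0],
        room_length=room[1],
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
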