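import numpy as np
import pytest

from bittercircuit.locomotor import Epoch, StimulusProtocol, Trajectory


def make_trajectory(
    forward=None,
    angular=None,
    x=None,
    y=None,
    n_frames=300,
    frame_rate=30.0,
    fly_id="fly",
):
    """Trajectory with constant defaults, overridable per series."""
    provided = [s for s in (forward, angular, x, y) if s is not None]
    n = len(provided[0]) if provided else n_frames
    forward = np.full(n, 5.0) if forward is None else np.asarray(forward, float)
    angular = np.zeros(n) if angular is None else np.asarray(angular, float)
    x = np.full(n, 1.0) if x is None else np.asarray(x, float)
    y = np.full(n, 1.0) if y is None else np.asarray(y, float)
    return Trajectory(
        fly_id=fly_id, frame_rate=frame_rate, x=x, y=y,
        forward_velocity=forward, angular_velocity=angular,
    )


def static_fly(quadrant: int, n_frames=300, frame_rate=30.0, fly_id="fly"):
    """Fly parked in the middle of one quadrant."""
    sx = {1: 1, 2: -1, 3: -1, 4: 1}[quadrant]
    sy = {1: 1, 2: 1, 3: -1, 4: -1}[quadrant]
    return make_trajectory(
        x=np.full(n_frames, 10.0 * sx),
        y=np.full(n_frames, 10.0 * sy),
        n_frames=n_frames,
        frame_rate=frame_rate,
        fly_id=fly_id,
    )


@pytest.fixture
def light_epoch():
    return Epoch(start=4.0, end=9.0, kind="light")


@pytest.fixture
def light_protocol(light_epoch):
    return StimulusProtocol([light_epoch])
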