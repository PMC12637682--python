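import numpy as np
import pytest

from ionflux.io_core import ChannelGeometry, IonTrajectory


@pytest.fixture
def geom():
    return ChannelGeometry()


def random_walk_trajectory(seed, n_ions=5, n_frames=400, box=(40.0, 40.0, 80.0),
                           step_sd=3.0):
    """Wrapped random-walk ions in a periodic box (no physics, no walls).

    Large steps make gate crossings, boundary passages and partial entries
    all common, which is exactly what the event state machine must sort out.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    walk = rng.uniform(-box / 2, box / 2, size=(n_ions, 1, 3)) + np.concatenate(
        [np.zeros((n_ions, 1, 3)),
         np.cumsum(rng.normal(0.0, step_sd, size=(n_ions, n_frames - 1, 3)),
                   axis=1)], axis=1)
    wrapped = (walk + box / 2) % box - box / 2
    return IonTrajectory(times=np.arange(n_frames, dtype=float),
                         box=np.tile(box, (n_frames, 1)),
                         positions=wrapped,
                         ion_ids=np.arange(n_ions))


@pytest.fixture
def rw_traj_factory():
    return random_walk_trajectory


def events_equal(a, b):
    """Exact field-wise equality of two event lists."""
    if len(a) != len(b):
        return False
    for x, y in zip(a, b):
        if (x.ion_id != y.ion_id or x.entry_ns != y.entry_ns
                or x.exit_ns != y.exit_ns or x.direction != y.direction):
            return False
    return True
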