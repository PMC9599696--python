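import numpy as np
import pytest

from fmascore import SkeletonSequence
from fmascore.io import JOINT_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_skeleton(positions_fn, n_frames=60, fps=30.0):
    """Skeleton sequence whose frame t is given by positions_fn(t) as a
    dict joint -> (x, y, z); unnamed joints sit at a default pose."""
    base = {name: (0.05 * i, 0.5, 0.0) for i, name in enumerate(JOINT_NAMES)}
    frames = []
    for t in range(n_frames):
        pose = dict(base)
        pose.update(positions_fn(t))
        frames.append([pose[name] for name in JOINT_NAMES])
    times = np.arange(n_frames) / fps
    return SkeletonSequence(times, np.asarray(frames, dtype=float), fps=fps)


@pytest.fixture
def static_skeleton():
    return make_skeleton(lambda t: {}, n_frames=60)
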