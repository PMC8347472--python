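import numpy as np
import pytest

from ergopose import (
    Keypoint,
    KeypointStream,
    SkeletonFrame,
    default_topology,
)


@pytest.fixture(scope="session")
def topology():
    return default_topology()


def make_frame(topology, frame_index=0, timestamp=0.0, absent=(), offsets=None):
    """A simple valid frame: keypoints on a grid, selected labels absent."""
    offsets = offsets or {}
    kps = []
    for i, name in enumerate(topology.names):
        if name in absent:
            kps.append(Keypoint.absent(name))
        else:
            dx, dy = offsets.get(name, (0.0, 0.0))
            kps.append(Keypoint(name=name, x=10.0 * i + dx, y=5.0 * i + dy, confidence=0.9))
    return SkeletonFrame(frame_index=frame_index, timestamp=timestamp, keypoints=tuple(kps))


@pytest.fixture
def grid_frame(topology):
    return make_frame(topology)


@pytest.fixture
def small_stream(topology):
    frames = [make_frame(topology, i, i / 30.0) for i in range(3)]
    return KeypointStream(topology=topology, frames=frames, source="test", frame_rate=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
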