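import numpy as np
import pytest

from voxnav import AgentProfile, Pose, Scene, SceneObject
from voxnav.scene import OccupancyGrid, Zone


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def origin_pose():
    return Pose(t=0.0, position=(0.0, 0.0, 0.0), yaw=0.0)


@pytest.fixture
def noiseless():
    return AgentProfile()


@pytest.fixture
def three_object_scene():
    """Objects at azimuths -60, 0, +60 (2 m) around the origin."""
    from voxnav.fixtures import position_at_azimuth

    objects = tuple(
        SceneObject(id=f"o{i}", label=lab, position=position_at_azimuth(az, 2.0))
        for i, (az, lab) in enumerate([(-60.0, "left"), (0.0, "mid"), (60.0, "right")])
    )
    return Scene(objects=objects)


@pytest.fixture
def empty_scene():
    return Scene(objects=())


def make_grid(rows, cols, blocked=(), cell=0.1, origin=(0.0, 0.0)):
    return OccupancyGrid(
        cell_size=cell, rows=rows, cols=cols, blocked=frozenset(blocked), origin=origin
    )
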