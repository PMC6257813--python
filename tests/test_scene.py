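import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxnav.angles import wrap_deg
from voxnav.scene import (
    GuidePath,
    OccupancyGrid,
    Pose,
    Scene,
    SceneObject,
    SceneValidationError,
    UndefinedAzimuthError,
    Waypoint,
    distance_to_nearest_obstacle,
    in_spotlight,
    load_scene,
    relative_azimuth,
    save_scene,
    scan_order,
    scene_from_dict,
    scene_to_dict,
)
from voxnav.fixtures import living_room_scene, position_at_azimuth

from conftest import make_grid


def _pose(yaw, pos=(0.0, 0.0, 0.0)):
    return Pose(t=0.0, position=pos, yaw=yaw)


def brute_force_wrap(a):
    """Independent angle-wrap oracle: step by 360 until in range."""
    while a > 180.0:
        a -= 360.0
    while a <= -180.0:
        a += 360.0
    return a


class TestPose:
    def test_yaw_normalized(self):
        assert _pose(270.0).yaw == pytest.approx(-90.0)

    def test_negative_time_rejected(self):
        with pytest.raises(SceneValidationError):
            Pose(t=-1.0, position=(0, 0, 0), yaw=0.0)


class TestRelativeAzimuth:
    def test_dead_ahead(self, origin_pose):
        assert relative_azimuth(origin_pose, (1.0, 0.0, 0.0)) == pytest.approx(0.0)

    def test_right_is_positive(self, origin_pose):
        assert relative_azimuth(origin_pose, (0.0, -1.0, 0.0)) == pytest.approx(90.0)
        assert relative_azimuth(origin_pose, (0.0, 1.0, 0.0)) == pytest.approx(-90.0)

    def test_wraparound(self):
        # yaw 170, target at absolute azimuth -170: 20 degrees to the right
        pose = _pose(170.0)
        point = position_at_azimuth(-170.0, 2.0)
        expected = brute_force_wrap(-170.0 - 170.0)
        assert expected == 20.0
        assert relative_azimuth(pose, point) == pytest.approx(20.0)

    def test_elevation_ignored(self, origin_pose):
        assert relative_azimuth(origin_pose, (1.0, 0.0, 5.0)) == pytest.approx(0.0)

    def test_degenerate_point_above(self, origin_pose):
        with pytest.raises(UndefinedAzimuthError):
            relative_azimuth(origin_pose, (0.0, 0.0, 2.0))

    @given(
        yaw=st.floats(-180, 180),
        az=st.floats(-179.9, 180),
        r=st.floats(0.5, 10),
    )
    @settings(max_examples=80)
    def test_opposite_pose_property(self, yaw, az, r):
        """Rotating the pose by 180 flips the relative azimuth by 180 mod 360."""
        point = position_at_azimuth(az, r)
        a1 = relative_azimuth(_pose(yaw), point)
        a2 = relative_azimuth(_pose(yaw + 180.0), point)
        assert abs(wrap_deg(a1 - a2)) == pytest.approx(180.0, abs=1e-6)

    @given(yaw=st.floats(-180, 180), az=st.floats(-179.9, 180))
    @settings(max_examples=80)
    def test_in_range(self, yaw, az):
        a = relative_azimuth(_pose(yaw), position_at_azimuth(az, 2.0))
        assert -180.0 < a <= 180.0


class TestSpotlight:
    def test_center(self, origin_pose):
        assert in_spotlight(origin_pose, (1, 0, 0), 30.0)

    def test_boundary_inclusive(self, origin_pose):
        point = position_at_azimuth(15.0, 2.0)
        assert in_spotlight(origin_pose, point, 30.0)

    def test_outside(self, origin_pose):
        assert not in_spotlight(origin_pose, position_at_azimuth(16.0, 2.0), 30.0)

    def test_bad_aperture(self, origin_pose):
        with pytest.raises(ValueError):
            in_spotlight(origin_pose, (1, 0, 0), 0.0)


class TestScanOrder:
    def test_left_to_right(self, three_object_scene, origin_pose):
        order = [o.label for o in scan_order(three_object_scene, origin_pose)]
        assert order == ["left", "mid", "right"]

    def test_singleton(self, origin_pose):
        scene = Scene(objects=(SceneObject(id="a", label="a", position=(1, 1, 0)),))
        assert [o.id for o in scan_order(scene, origin_pose)] == ["a"]

    def test_empty(self, empty_scene, origin_pose):
        assert scan_order(empty_scene, origin_pose) == []

    def test_tie_break_by_id(self, origin_pose):
        p = position_at_azimuth(20.0, 2.0)
        scene = Scene(
            objects=(
                SceneObject(id="zeta", label="z", position=p),
                SceneObject(id="alpha", label="a", position=p),
            )
        )
        assert [o.id for o in scan_order(scene, origin_pose)] == ["alpha", "zeta"]

    @given(yaws=st.floats(-180, 180), rot=st.floats(-180, 180))
    @settings(max_examples=40)
    def test_rotation_invariance(self, yaws, rot):
        """Scan order is unchanged when scene and pose rotate together."""
        azs = [-60.0, -25.0, 10.0, 95.0]
        base = Scene(
            objects=tuple(
                SceneObject(id=f"o{i}", label=f"o{i}", position=position_at_azimuth(a + yaws, 2.0))
                for i, a in enumerate(azs)
            )
        )
        rotated = Scene(
            objects=tuple(
                SceneObject(id=f"o{i}", label=f"o{i}", position=position_at_azimuth(a + yaws + rot, 2.0))
                for i, a in enumerate(azs)
            )
        )
        ids1 = [o.id for o in scan_order(base, _pose(yaws))]
        ids2 = [o.id for o in scan_order(rotated, _pose(yaws + rot))]
        assert ids1 == ids2
        assert sorted(ids1) == [f"o{i}" for i in range(4)]  # permutation


def brute_force_obstacle_distance(grid, x, y):
    """Exhaustive all-cells oracle for the nearest blocked-cell distance."""
    best = math.inf
    for (r, c) in grid.blocked:
        x0 = grid.origin[0] + c * grid.cell_size
        y0 = grid.origin[1] + r * grid.cell_size
        dx = max(x0 - x, 0.0, x - (x0 + grid.cell_size))
        dy = max(y0 - y, 0.0, y - (y0 + grid.cell_size))
        best = min(best, math.hypot(dx, dy))
    return best


class TestObstacleDistance:
    def test_empty_grid_is_inf(self):
        scene = Scene(objects=(), grid=make_grid(10, 10))
        assert distance_to_nearest_obstacle(scene, (0.5, 0.5, 0.0)) == math.inf

    def test_inside_blocked_cell(self):
        scene = Scene(objects=(), grid=make_grid(10, 10, blocked={(5, 5)}))
        assert distance_to_nearest_obstacle(scene, (0.55, 0.55, 0.0)) == 0.0

    def test_one_meter_from_cell_center(self):
        # blocked cell centered at (0.55, 0.55); query 1 m from its center:
        # distance to the boundary is 1.0 minus half the cell size
        scene = Scene(objects=(), grid=make_grid(20, 20, blocked={(5, 5)}, cell=0.1, origin=(0.0, 0.0)))
        d = distance_to_nearest_obstacle(scene, (0.55, 1.55, 0.0))
        assert d == pytest.approx(1.0 - 0.05, abs=1e-9)

    def test_outside_bounds_raises(self):
        scene = Scene(objects=(), grid=make_grid(10, 10))
        with pytest.raises(ValueError):
            distance_to_nearest_obstacle(scene, (100.0, 0.0, 0.0))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rows, cols = int(rng.integers(2, 50)), int(rng.integers(2, 50))
        n_blocked = int(rng.integers(0, 30))
        blocked = {
            (int(rng.integers(rows)), int(rng.integers(cols))) for _ in range(n_blocked)
        }
        grid = make_grid(rows, cols, blocked=blocked)
        scene = Scene(objects=(), grid=grid)
        x = float(rng.uniform(0, cols * grid.cell_size))
        y = float(rng.uniform(0, rows * grid.cell_size))
        got = distance_to_nearest_obstacle(scene, (x, y, 0.0))
        assert got == pytest.approx(brute_force_obstacle_distance(grid, x, y), abs=1e-9)


class TestSceneConfig:
    def test_living_room_has_16_objects(self):
        assert len(living_room_scene().objects) == 16

    def test_round_trip_identity(self, tmp_path):
        scene = living_room_scene()
        path = tmp_path / "scene.json"
        save_scene(scene, path)
        again = load_scene(path)
        assert scene_to_dict(again) == scene_to_dict(scene)

    def test_empty_objects_valid(self):
        scene = scene_from_dict({"objects": []})
        assert scene.objects == ()

    def test_negative_radius_rejected(self):
        cfg = {"objects": [{"id": "a", "label": "a", "position": [1, 1, 0], "radius": -1.0}]}
        with pytest.raises(SceneValidationError, match="radius"):
            scene_from_dict(cfg)

    def test_missing_field_named(self):
        with pytest.raises(SceneValidationError, match="label"):
            scene_from_dict({"objects": [{"id": "a", "position": [1, 1, 0]}]})

    def test_object_outside_bounds_rejected(self):
        cfg = {
            "objects": [{"id": "a", "label": "a", "position": [99.0, 0.0, 0.0]}],
            "grid": {"cell_size": 0.1, "rows": 10, "cols": 10, "origin": [0, 0]},
        }
        with pytest.raises(SceneValidationError, match="position"):
            scene_from_dict(cfg)


class TestGuidePathGeometry:
    def test_needs_two_waypoints(self):
        with pytest.raises(SceneValidationError):
            GuidePath(waypoints=(Waypoint(position=(0, 0, 0)),))

    def test_distinct_consecutive(self):
        with pytest.raises(SceneValidationError):
            GuidePath(
                waypoints=(Waypoint(position=(0, 0, 0)), Waypoint(position=(0, 0, 0)))
            )

    def test_project_and_point_at(self):
        path = GuidePath(
            waypoints=(
                Waypoint(position=(0, 0, 0)),
                Waypoint(position=(4, 0, 0)),
                Waypoint(position=(4, 3, 0)),
            )
        )
        assert path.length() == pytest.approx(7.0)
        np.testing.assert_allclose(path.point_at(5.0), [4, 1, 0])
        assert path.project((2.0, 1.0, 0.0)) == pytest.approx(2.0)
        # monotone projection cannot go backward
        s = path.project_monotone((1.0, 0.5, 0.0), s_prev=3.0)
        assert s >= 3.0
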