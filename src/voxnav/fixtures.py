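"""Bundled deterministic scene and path fixtures for the task battery.

All geometries follow the published task layouts: the five-object half
circle for the memory task, the four-chair arena, the nine-waypoint
building route of 36.4 m, and the 16-object living room used by the
benchmark tasks.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List

import numpy as np

from .scene import (
    GuidePath,
    OccupancyGrid,
    Scene,
    SceneObject,
    Waypoint,
    Zone,
    save_scene,
)

__all__ = [
    "position_at_azimuth",
    "memory_scene",
    "arena_scene",
    "chair_position",
    "building_path",
    "building_scene",
    "living_room_scene",
    "fixture_generator",
    "FIXTURE_NAMES",
    "SONAR_SECTOR_DEG",
    "MEMORY_BLOCK_LABELS",
    "MEMORY_AZIMUTHS",
]

#: reference sector marked by sonar beeps during the memory task
SONAR_SECTOR_DEG = (-7.5, 7.5)

#: left-to-right object orderings of the two memory-task blocks
MEMORY_BLOCK_LABELS = {
    1: ("piano", "table", "chair", "lamp", "trash bin"),
    2: ("trash bin", "piano", "table", "chair", "lamp"),
}

MEMORY_AZIMUTHS = (-60.0, -30.0, 0.0, 30.0, 60.0)


def position_at_azimuth(azimuth_deg: float, distance: float, z: float = 0.0) -> np.ndarray:
    """World position at a given azimuth/distance from the origin for a
    listener facing +x (positive azimuth to the right)."""
    r = math.radians(azimuth_deg)
    return np.array([distance * math.cos(r), -distance * math.sin(r), z])


def _slug(label: str) -> str:
    return label.replace(" ", "_")


def memory_scene(block: int = 1, distance: float = 2.0) -> Scene:
    """Five objects on a half circle, 30 degrees apart, at ``distance`` m."""
    labels = MEMORY_BLOCK_LABELS[block]
    objects = tuple(
        SceneObject(
            id=_slug(label),
            label=label,
            position=position_at_azimuth(az, distance),
            radius=0.3,
        )
        for az, label in zip(MEMORY_AZIMUTHS, labels)
    )
    grid = OccupancyGrid(cell_size=0.1, rows=100, cols=100, origin=(-5.0, -5.0))
    return Scene(objects=objects, grid=grid, start_zone=Zone(center=(0, 0, 0), radius=0.5))


CHAIR_AZIMUTHS = (0.0, 90.0, 180.0, 270.0)


def chair_position(azimuth_deg: float, distance: float = 2.0) -> np.ndarray:
    return position_at_azimuth(azimuth_deg, distance)


def arena_scene(chair_azimuth: float = 0.0, distance: float = 2.0) -> Scene:
    """Direct-navigation arena: a single chair at 2 m from the center, a
    1 m diameter starting zone in the middle."""
    chair = SceneObject(
        id="chair", label="chair", position=chair_position(chair_azimuth, distance), radius=0.5
    )
    grid = OccupancyGrid(cell_size=0.1, rows=100, cols=100, origin=(-5.0, -5.0))
    return Scene(objects=(chair,), grid=grid, start_zone=Zone(center=(0, 0, 0), radius=0.5))


def building_path(total_length: float = 36.4) -> GuidePath:
    """Nine-waypoint route through lobby, stairwell and hallway whose
    polyline length equals ``total_length`` meters exactly (the last leg is
    stretched to absorb rounding)."""
    rise = 1.8  # one flight of stairs
    pts = [
        np.array([0.0, 0.0, 0.0]),
        np.array([6.0, 0.0, 0.0]),
        np.array([6.0, -4.0, 0.0]),
        np.array([9.0, -4.0, rise]),
        np.array([9.0, -2.0, rise]),
        np.array([6.0, -2.0, 2 * rise]),
        np.array([6.0, 2.0, 2 * rise]),
        np.array([16.0, 2.0, 2 * rise]),
    ]
    fixed = sum(float(np.linalg.norm(b - a)) for a, b in zip(pts, pts[1:]))
    last_leg = total_length - fixed
    if last_leg <= 0:
        raise ValueError("total_length too short for the fixed layout")
    pts.append(pts[-1] + np.array([0.0, last_leg, 0.0]))

    turns = ["none", "right", "left", "left", "left", "right", "right", "left", "none"]
    stairs = [False, False, True, True, True, False, False, False, False]
    segments = {0: "lobby", 2: "stairwell", 5: "hallway"}
    waypoints = tuple(
        Waypoint(position=p, turn=turns[i], stairs=stairs[i], segment=segments.get(i))
        for i, p in enumerate(pts)
    )
    return GuidePath(waypoints=waypoints, arrival_radius=1.2)


def building_scene() -> Scene:
    path = building_path()
    grid = OccupancyGrid(cell_size=0.1, rows=160, cols=220, origin=(-2.0, -6.0))
    return Scene(
        objects=(),
        grid=grid,
        start_zone=Zone(center=path.waypoints[0].position, radius=1.2),
        path=path,
    )


_LIVING_ROOM_LAYOUT = [
    # (label, x, y, z, radius)
    ("sofa", -3.5, 2.5, 0.4, 0.8),
    ("coffee table", -2.0, 1.5, 0.3, 0.5),
    ("dining table", 3.0, 2.5, 0.5, 0.7),
    ("chair", 2.0, 0.0, 0.4, 0.5),
    ("tv", -4.0, -1.0, 0.8, 0.5),
    ("lamp", -1.0, 3.8, 1.2, 0.3),
    ("bookshelf", 4.2, -2.0, 1.0, 0.5),
    ("piano", 1.5, -3.5, 0.8, 0.7),
    ("plant", -3.0, -3.5, 0.6, 0.3),
    ("rug", 0.0, 1.0, 0.0, 0.9),
    ("door", 0.5, -4.5, 1.0, 0.4),
    ("window", 4.5, 1.0, 1.2, 0.4),
    ("cabinet", -4.2, 0.5, 0.7, 0.5),
    ("vase", 3.8, 4.0, 0.5, 0.2),
    ("clock", 0.0, 4.5, 1.5, 0.2),
    ("trash bin", -1.5, -2.0, 0.3, 0.3),
]


def living_room_scene() -> Scene:
    """The benchmark living room: 16 labelled objects in a 10 m x 10 m room."""
    objects = tuple(
        SceneObject(id=_slug(label), label=label, position=(x, y, z), radius=r)
        for label, x, y, z, r in _LIVING_ROOM_LAYOUT
    )
    grid = OccupancyGrid(cell_size=0.1, rows=100, cols=100, origin=(-5.0, -5.0))
    return Scene(objects=objects, grid=grid, start_zone=Zone(center=(0, 0, 0), radius=0.5))


FIXTURE_NAMES = ("memory-block1", "memory-block2", "arena", "building", "living-room")


def _build(name: str) -> Scene:
    if name == "memory-block1":
        return memory_scene(1)
    if name == "memory-block2":
        return memory_scene(2)
    if name == "arena":
        return arena_scene()
    if name == "building":
        return building_scene()
    if name == "living-room":
        return living_room_scene()
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def fixture_generator(name: str = "all", out_dir=None) -> Dict[str, Scene]:
    """Regenerate bundled fixtures deterministically.  Writes
    ``<name>.json`` files when ``out_dir`` is given; returns the scenes."""
    names = FIXTURE_NAMES if name == "all" else (name,)
    scenes = {n: _build(n) for n in names}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for n, scene in scenes.items():
            save_scene(scene, out / f"{n}.json")
    return scenes
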