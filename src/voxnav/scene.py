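"""Geometric world model: poses, scenes, occupancy grids and guide paths.

Coordinate system: right-handed with x/y horizontal and z up.  Yaw is the
head's horizontal facing angle measured from +x, positive clockwise viewed
from above, so positive relative azimuth means "to the listener's right".
Azimuths are computed in the horizontal plane only; elevation is ignored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .angles import absolute_azimuth, wrap_deg

__all__ = [
    "Pose",
    "SceneObject",
    "OccupancyGrid",
    "Zone",
    "Waypoint",
    "GuidePath",
    "Scene",
    "SceneValidationError",
    "UndefinedAzimuthError",
    "relative_azimuth",
    "in_spotlight",
    "scan_order",
    "distance_to_nearest_obstacle",
    "nearest_obstacle_point",
    "load_scene",
    "save_scene",
    "scene_from_dict",
    "scene_to_dict",
]


class SceneValidationError(ValueError):
    """A scene/path configuration violated the schema; names the bad field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class UndefinedAzimuthError(ValueError):
    """Raised when a point has no defined horizontal azimuth (directly
    above/below the head)."""


@dataclass(frozen=True)
class Pose:
    """Time-stamped head position and orientation.

    ``yaw`` is normalized to (-180, 180] on construction; ``pitch``/``roll``
    are carried through for logging but play no role in azimuth queries.
    """

    t: float
    position: np.ndarray
    yaw: float
    pitch: float = 0.0
    roll: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise SceneValidationError("position", "must be a 3-vector")
        if self.t < 0:
            raise SceneValidationError("t", "must be non-negative")
        object.__setattr__(self, "yaw", float(wrap_deg(self.yaw)))

    def as_row(self) -> list:
        return [self.t, *self.position.tolist(), self.yaw, self.pitch, self.roll]


@dataclass(frozen=True)
class SceneObject:
    """A labelled virtual object with a trigger/collision footprint."""

    id: str
    label: str
    position: np.ndarray
    radius: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise SceneValidationError("objects.position", "must be a 3-vector")
        if not self.label:
            raise SceneValidationError("objects.label", "must be non-empty")
        if not self.id:
            raise SceneValidationError("objects.id", "must be non-empty")
        if not self.radius > 0:
            raise SceneValidationError("objects.radius", "must be > 0")


@dataclass(frozen=True)
class OccupancyGrid:
    """2D boolean obstacle map.

    Cell (row, col) spans ``x in [x0 + col*s, x0 + (col+1)*s]`` and
    ``y in [y0 + row*s, y0 + (row+1)*s]`` where ``s`` is ``cell_size`` and
    (x0, y0) is ``origin``.
    """

    cell_size: float
    rows: int
    cols: int
    blocked: frozenset = frozenset()
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        if not self.cell_size > 0:
            raise SceneValidationError("grid.cell_size", "must be > 0")
        if self.rows < 1 or self.cols < 1:
            raise SceneValidationError("grid.rows/cols", "must be >= 1")
        blocked = frozenset((int(r), int(c)) for r, c in self.blocked)
        for r, c in blocked:
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise SceneValidationError("grid.blocked", f"cell {(r, c)} outside grid")
        object.__setattr__(self, "blocked", blocked)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def x_max(self) -> float:
        return self.origin[0] + self.cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin[1] + self.rows * self.cell_size

    def contains(self, position) -> bool:
        x, y = float(position[0]), float(position[1])
        return (self.origin[0] <= x <= self.x_max) and (self.origin[1] <= y <= self.y_max)

    def cell_of(self, position) -> tuple:
        x, y = float(position[0]), float(position[1])
        c = min(int((x - self.origin[0]) / self.cell_size), self.cols - 1)
        r = min(int((y - self.origin[1]) / self.cell_size), self.rows - 1)
        return (max(r, 0), max(c, 0))

    def cell_center(self, cell) -> np.ndarray:
        r, c = cell
        return np.array(
            [
                self.origin[0] + (c + 0.5) * self.cell_size,
                self.origin[1] + (r + 0.5) * self.cell_size,
            ]
        )

    def is_free(self, cell) -> bool:
        return cell not in self.blocked


@dataclass(frozen=True)
class Zone:
    """A circular region (e.g. start zone)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise SceneValidationError("start_zone.center", "must be a 3-vector")
        if not self.radius > 0:
            raise SceneValidationError("start_zone.radius", "must be > 0")

    def contains(self, position) -> bool:
        p = np.asarray(position, dtype=float)
        return float(np.linalg.norm(p[:2] - self.center[:2])) <= self.radius


TURN_VALUES = ("left", "right", "none")


@dataclass(frozen=True)
class Waypoint:
    """One anchor of a guide path, optionally annotated with a turn
    direction, a stairs warning, and the name of the route segment that
    begins at this waypoint."""

    position: np.ndarray
    turn: str = "none"
    stairs: bool = False
    segment: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise SceneValidationError("waypoints.xyz", "must be a 3-vector")
        if self.turn not in TURN_VALUES:
            raise SceneValidationError("waypoints.turn", f"must be one of {TURN_VALUES}")


@dataclass(frozen=True)
class GuidePath:
    """Ordered waypoint polyline followed by the virtual guide."""

    waypoints: tuple
    arrival_radius: float = 1.2

    def __post_init__(self):
        wps = tuple(self.waypoints)
        if len(wps) < 2:
            raise SceneValidationError("waypoints", "need at least 2 waypoints")
        for a, b in zip(wps, wps[1:]):
            if np.allclose(a.position, b.position):
                raise SceneValidationError("waypoints", "consecutive waypoints must be distinct")
        if not self.arrival_radius > 0:
            raise SceneValidationError("arrival_radius", "must be > 0")
        object.__setattr__(self, "waypoints", wps)

    @property
    def points(self) -> np.ndarray:
        return np.array([w.position for w in self.waypoints])

    def segment_lengths(self) -> np.ndarray:
        return self._geometry[2]

    def length(self) -> float:
        return float(self._geometry[3][-1])

    def cumulative_lengths(self) -> np.ndarray:
        """Arc length at each waypoint, starting at 0."""
        return self._geometry[3]

    def point_at(self, s: float) -> np.ndarray:
        """Position at arc length ``s`` along the polyline (clamped)."""
        p, ab, lens, cum = self._geometry
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(cum) - 2)
        seg = cum[i + 1] - cum[i]
        frac = 0.0 if seg == 0 else (s - cum[i]) / seg
        return p[i] + frac * ab[i]

    def project(self, position) -> float:
        """Arc length of the closest point on the polyline to ``position``.

        Projection is 3D; ties resolve to the earliest arc length.
        """
        return self._project(position, 0.0)

    def project_monotone(self, position, s_prev: float) -> float:
        """Continuity-constrained projection: the nearest point on the
        polyline at arc length >= ``s_prev``.

        Switchback routes make the plain nearest-point projection ambiguous
        (it can jump between distant branches); constraining it to move
        forward from the previous value yields a stable measure of the
        user's progress along the path.
        """
        return self._project(position, float(s_prev))

    @property
    def _geometry(self):
        """Cached (points, segment vectors, lengths, cumulative lengths)."""
        cached = self.__dict__.get("_geom_cache")
        if cached is None:
            p = self.points
            ab = np.diff(p, axis=0)
            lens = np.linalg.norm(ab, axis=1)
            cum = np.concatenate([[0.0], np.cumsum(lens)])
            cached = (p, ab, lens, cum)
            self.__dict__["_geom_cache"] = cached
        return cached

    def _project(self, position, s_min: float) -> float:
        q = np.asarray(position, dtype=float)
        p, ab, lens, cum = self._geometry
        s_min = float(np.clip(s_min, 0.0, cum[-1]))
        denom = np.where(lens > 0, lens * lens, 1.0)
        tt = ((q - p[:-1]) * ab).sum(axis=1) / denom
        t_lo = np.clip((s_min - cum[:-1]) / np.where(lens > 0, lens, 1.0), 0.0, 1.0)
        tt = np.clip(tt, t_lo, 1.0)
        proj = p[:-1] + tt[:, None] * ab
        d = np.linalg.norm(q - proj, axis=1)
        d[cum[1:] < s_min] = np.inf
        i = int(np.argmin(d))  # argmin takes the earliest on exact ties
        if not np.isfinite(d[i]):
            return s_min
        return float(cum[i] + tt[i] * lens[i])


@dataclass(frozen=True)
class Scene:
    """World model: labelled objects, an obstacle grid, and a start zone."""

    objects: tuple = ()
    grid: OccupancyGrid = OccupancyGrid(cell_size=0.1, rows=100, cols=100, origin=(-5.0, -5.0))
    start_zone: Optional[Zone] = None
    path: Optional[GuidePath] = None

    def __post_init__(self):
        objs = tuple(self.objects)
        ids = [o.id for o in objs]
        if len(set(ids)) != len(ids):
            raise SceneValidationError("objects.id", "ids must be unique")
        for o in objs:
            if not self.grid.contains(o.position):
                raise SceneValidationError(
                    "objects.position", f"object {o.id!r} lies outside grid bounds"
                )
        object.__setattr__(self, "objects", objs)

    def object_by_id(self, object_id: str) -> SceneObject:
        for o in self.objects:
            if o.id == object_id:
                return o
        raise KeyError(f"unknown object id: {object_id!r}")


# ---------------------------------------------------------------------------
# Angular / distance queries
# ---------------------------------------------------------------------------

def relative_azimuth(pose: Pose, point) -> float:
    """Horizontal angle of ``point`` relative to the pose's facing direction.

    Returns degrees in (-180, 180]; 0 means dead ahead and positive values
    are to the listener's right.  Raises :class:`UndefinedAzimuthError` for a
    point directly above/below the head (no horizontal offset).
    """
    p = np.asarray(point, dtype=float)
    dx = p[0] - pose.position[0]
    dy = p[1] - pose.position[1]
    if math.hypot(dx, dy) < 1e-12:
        raise UndefinedAzimuthError("point has no horizontal offset from the pose")
    return float(wrap_deg(absolute_azimuth(dx, dy) - pose.yaw))


def in_spotlight(pose: Pose, point, aperture_deg: float) -> bool:
    """True iff ``point`` lies inside the spotlight cone about the facing
    direction.  The boundary (exactly half the aperture) is inclusive."""
    if not (0 < aperture_deg < 360):
        raise ValueError("aperture_deg must be in (0, 360)")
    return abs(relative_azimuth(pose, point)) <= aperture_deg / 2.0


def scan_order(scene: Scene, pose: Pose) -> list:
    """Objects sorted left-to-right by relative azimuth (ties by id)."""
    return sorted(
        scene.objects, key=lambda o: (relative_azimuth(pose, o.position), o.id)
    )


def _rect_distance(x: float, y: float, grid: OccupancyGrid, cell) -> float:
    r, c = cell
    x0 = grid.origin[0] + c * grid.cell_size
    y0 = grid.origin[1] + r * grid.cell_size
    dx = max(x0 - x, 0.0, x - (x0 + grid.cell_size))
    dy = max(y0 - y, 0.0, y - (y0 + grid.cell_size))
    return math.hypot(dx, dy)


def distance_to_nearest_obstacle(scene: Scene, position) -> float:
    """Euclidean distance from ``position`` to the nearest blocked cell
    boundary; inf if the grid has no obstacles; 0 inside a blocked cell."""
    return nearest_obstacle_point(scene, position)[0]


def nearest_obstacle_point(scene: Scene, position):
    """(distance, closest point on the nearest blocked cell) for ``position``.

    Returns (inf, None) when the grid has no obstacles.
    """
    p = np.asarray(position, dtype=float)
    grid = scene.grid
    if not grid.contains(p):
        raise ValueError(f"position {p[:2]} outside grid bounds")
    if not grid.blocked:
        return math.inf, None
    x, y = float(p[0]), float(p[1])
    best_d, best_cell = math.inf, None
    for cell in grid.blocked:
        d = _rect_distance(x, y, grid, cell)
        if d < best_d:
            best_d, best_cell = d, cell
            if d == 0.0:
                break
    r, c = best_cell
    x0 = grid.origin[0] + c * grid.cell_size
    y0 = grid.origin[1] + r * grid.cell_size
    cx = min(max(x, x0), x0 + grid.cell_size)
    cy = min(max(y, y0), y0 + grid.cell_size)
    z = float(p[2]) if p.shape[0] > 2 else 0.0
    return best_d, np.array([cx, cy, z])


# ---------------------------------------------------------------------------
# Config (de)serialization — JSON schema documented in the README
# ---------------------------------------------------------------------------

def _require(d: dict, key: str, context: str):
    if key not in d:
        raise SceneValidationError(f"{context}{key}", "missing required field")
    return d[key]


def scene_from_dict(cfg: dict) -> Scene:
    """Build a Scene from a config mapping, validating every field."""
    if not isinstance(cfg, dict):
        raise SceneValidationError("<root>", "config must be a mapping")
    objects = []
    for i, o in enumerate(cfg.get("objects", [])):
        ctx = f"objects[{i}]."
        objects.append(
            SceneObject(
                id=str(_require(o, "id", ctx)),
                label=str(_require(o, "label", ctx)),
                position=_require(o, "position", ctx),
                radius=float(o.get("radius", 0.5)),
            )
        )
    g = cfg.get("grid", {})
    grid = OccupancyGrid(
        cell_size=float(g.get("cell_size", 0.1)),
        rows=int(g.get("rows", 100)),
        cols=int(g.get("cols", 100)),
        blocked=frozenset(tuple(c) for c in g.get("blocked", [])),
        origin=tuple(g.get("origin", (-5.0, -5.0))),
    )
    zone = None
    if "start_zone" in cfg and cfg["start_zone"] is not None:
        z = cfg["start_zone"]
        zone = Zone(center=_require(z, "center", "start_zone."), radius=float(_require(z, "radius", "start_zone.")))
    path = None
    if cfg.get("waypoints"):
        wps = []
        for i, w in enumerate(cfg["waypoints"]):
            ctx = f"waypoints[{i}]."
            wps.append(
                Waypoint(
                    position=_require(w, "xyz", ctx),
                    turn=w.get("turn", "none"),
                    stairs=bool(w.get("stairs", False)),
                    segment=w.get("segment"),
                )
            )
        path = GuidePath(waypoints=tuple(wps), arrival_radius=float(cfg.get("arrival_radius", 1.2)))
    return Scene(objects=tuple(objects), grid=grid, start_zone=zone, path=path)


def scene_to_dict(scene: Scene) -> dict:
    cfg: dict = {
        "objects": [
            {
                "id": o.id,
                "label": o.label,
                "position": [float(v) for v in o.position],
                "radius": float(o.radius),
            }
            for o in scene.objects
        ],
        "grid": {
            "cell_size": scene.grid.cell_size,
            "rows": scene.grid.rows,
            "cols": scene.grid.cols,
            "blocked": sorted([r, c] for r, c in scene.grid.blocked),
            "origin": list(scene.grid.origin),
        },
    }
    if scene.start_zone is not None:
        cfg["start_zone"] = {
            "center": [float(v) for v in scene.start_zone.center],
            "radius": float(scene.start_zone.radius),
        }
    if scene.path is not None:
        cfg["waypoints"] = [
            {
                "xyz": [float(v) for v in w.position],
                "turn": w.turn,
                "stairs": w.stairs,
                **({"segment": w.segment} if w.segment is not None else {}),
            }
            for w in scene.path.waypoints
        ]
        cfg["arrival_radius"] = float(scene.path.arrival_radius)
    return cfg


def load_scene(source: Union[str, Path, dict]) -> Scene:
    """Load a Scene from a JSON file path or an already-parsed mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = json.load(fh)
    else:
        cfg = source
    return scene_from_dict(cfg)


def save_scene(scene: Scene, path: Union[str, Path, None] = None) -> dict:
    """Serialize a Scene; writes JSON if ``path`` is given, returns the dict."""
    cfg = scene_to_dict(scene)
    if path is not None:
        with open(path, "w") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return cfg
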