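"""Virtual-guide controller and automated wayfinding.

The guide walks a waypoint polyline ahead of the user, calling "follow me"
every ``call_interval`` seconds, and only proceeds while the user keeps up.
"Ahead" is measured along the path (arc length), not Euclidean distance.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .angles import absolute_azimuth, wrap_deg
from .scene import GuidePath, OccupancyGrid, Pose, SceneValidationError, Waypoint
from .sonify import AudioEvent

__all__ = [
    "GuideState",
    "GuideParams",
    "NoPathError",
    "update_guide",
    "turn_by_turn",
    "compute_path",
    "astar_cells",
]


class NoPathError(RuntimeError):
    """No navigable route exists between the requested endpoints."""


@dataclass(frozen=True)
class GuideParams:
    """Tunable guide behavior; defaults follow the published protocol where
    stated (2 s call period, 1 m lead, 1.2 m arrival radius)."""

    call_interval: float = 2.0
    lead_distance: float = 1.0
    follow_gate: float = 1.0   # guide proceeds only while user is closer than this
    guide_speed: float = 1.2   # m/s cap while leading
    instruction_lead: float = 2.0  # path-distance before a waypoint at which to instruct


DEFAULT_GUIDE_PARAMS = GuideParams()


@dataclass(frozen=True)
class GuideState:
    """Guide controller state for one trial."""

    guide_s: float = 0.0               # arc length of the guide along the path
    time_since_call: float = 0.0
    status: str = "leading"            # leading | waiting | arrived
    instructions_issued: frozenset = frozenset()
    user_s: float = 0.0                # monotone track of the user's path progress

    def segment_index(self, path: GuidePath) -> int:
        """Index of the waypoint leg the guide is currently on."""
        cum = path.cumulative_lengths()
        i = int(np.searchsorted(cum, self.guide_s, side="right") - 1)
        return int(np.clip(i, 0, len(path.waypoints) - 2))

    def guide_position(self, path: GuidePath) -> np.ndarray:
        return path.point_at(self.guide_s)


def _instruction_label(wp: Waypoint) -> str:
    parts = []
    if wp.turn != "none":
        parts.append(f"turn {wp.turn}")
    if wp.stairs:
        parts.append("stairs ahead")
    if not parts:
        parts.append("continue straight")
    return ", ".join(parts)


def update_guide(
    state: GuideState,
    path: GuidePath,
    user_position,
    dt: float,
    t: float = 0.0,
    params: GuideParams = DEFAULT_GUIDE_PARAMS,
) -> Tuple[GuideState, List[AudioEvent]]:
    """Advance the guide by one time step.

    Returns the new state plus any events emitted during the step:
    waypoint instructions (each intermediate waypoint exactly once),
    periodic "follow me" calls, and the one-time arrival feedback.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.status == "arrived":
        return state, []

    user = np.asarray(user_position, dtype=float)
    events: List[AudioEvent] = []
    cum = path.cumulative_lengths()
    total = float(cum[-1])

    # monotone path progress of the user (stable across switchbacks)
    user_s = path.project_monotone(user, state.user_s)

    # (c) one-shot turn/stairs instructions just before waypoints 2..n-1
    issued = set(state.instructions_issued)
    for i in range(1, len(path.waypoints) - 1):
        if i in issued:
            continue
        if cum[i] - user_s <= params.instruction_lead:
            wp = path.waypoints[i]
            events.append(
                AudioEvent(
                    t=t,
                    kind="instruction",
                    source_position=wp.position,
                    label=_instruction_label(wp),
                )
            )
            issued.add(i)

    # (d) arrival: inclusive at the arrival radius around the final waypoint
    final_wp = path.waypoints[-1].position
    if float(np.linalg.norm(user - final_wp)) <= path.arrival_radius:
        events.append(
            AudioEvent(
                t=t, kind="feedback", source_position=final_wp, label="You have arrived"
            )
        )
        new_state = replace(
            state,
            status="arrived",
            instructions_issued=frozenset(issued),
            user_s=user_s,
        )
        return new_state, events

    # (a) motion: advance only while the user keeps up, never more than
    # lead_distance ahead along the path
    guide_pos = path.point_at(state.guide_s)
    user_close = float(np.linalg.norm(user - guide_pos)) < params.follow_gate
    guide_s = state.guide_s
    if user_close and guide_s < total:
        cap = min(user_s + params.lead_distance, total)
        guide_s = float(min(max(guide_s, 0.0) + params.guide_speed * dt, max(cap, guide_s)))
        status = "leading"
    else:
        status = "waiting" if not user_close else "leading"

    # (b) periodic follow-me call; subtractive reset keeps spacing exact
    time_since_call = state.time_since_call + dt
    if time_since_call >= params.call_interval - 1e-9:
        time_since_call -= params.call_interval
        events.append(
            AudioEvent(
                t=t,
                kind="follow_me",
                source_position=path.point_at(guide_s),
                label="follow me",
            )
        )

    new_state = GuideState(
        guide_s=guide_s,
        time_since_call=time_since_call,
        status=status,
        instructions_issued=frozenset(issued),
        user_s=user_s,
    )
    return new_state, events


def turn_by_turn(path: GuidePath, user_pose: Pose, arrival_radius: Optional[float] = None) -> str:
    """Verbal instruction: distance to the current target waypoint plus the
    turn needed (from the user's heading) to orient toward the next leg."""
    radius = path.arrival_radius if arrival_radius is None else arrival_radius
    final_wp = path.waypoints[-1].position
    if float(np.linalg.norm(user_pose.position - final_wp)) <= radius:
        return "You have arrived"
    cum = path.cumulative_lengths()
    user_s = path.project(user_pose.position)
    idx = int(np.searchsorted(cum, user_s + 1e-9, side="right"))
    idx = min(idx, len(path.waypoints) - 1)
    wp = path.waypoints[idx].position
    dist = float(np.linalg.norm((user_pose.position - wp)[:2]))
    dist_txt = f"{round(dist, 1):.1f} m"
    if idx >= len(path.waypoints) - 1:
        return dist_txt  # final leg: distance only
    nxt = path.waypoints[idx + 1].position
    leg_az = absolute_azimuth(nxt[0] - wp[0], nxt[1] - wp[1])
    turn = float(wrap_deg(leg_az - user_pose.yaw))
    if abs(turn) < 1.0:
        return f"{dist_txt}, then continue straight"
    side = "right" if turn > 0 else "left"
    return f"{dist_txt}, then turn {side} {abs(round(turn)):.0f}°"


# ---------------------------------------------------------------------------
# Automated wayfinding: A* on the occupancy grid
# ---------------------------------------------------------------------------

_MOVES = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def astar_cells(grid: OccupancyGrid, start_cell, goal_cell) -> List[tuple]:
    """Shortest 8-connected path (unit cost per move) between two free
    cells; raises :class:`NoPathError` when the goal is unreachable."""
    if not grid.is_free(start_cell):
        raise NoPathError(f"start cell {start_cell} is blocked")
    if not grid.is_free(goal_cell):
        raise NoPathError(f"goal cell {goal_cell} is blocked")

    def h(cell):  # Chebyshev distance: admissible for unit-cost 8-connectivity
        return max(abs(cell[0] - goal_cell[0]), abs(cell[1] - goal_cell[1]))

    open_heap = [(h(start_cell), 0, 0.0, start_cell)]
    g = {start_cell: 0.0}
    came: dict = {}
    tie = 0
    while open_heap:
        _, _, g_here, cell = heapq.heappop(open_heap)
        if cell == goal_cell:
            out = [cell]
            while cell in came:
                cell = came[cell]
                out.append(cell)
            return out[::-1]
        if g_here > g[cell]:
            continue
        for dr, dc in _MOVES:
            nb = (cell[0] + dr, cell[1] + dc)
            if not (0 <= nb[0] < grid.rows and 0 <= nb[1] < grid.cols):
                continue
            if not grid.is_free(nb):
                continue
            # unit cost per move; vanishing diagonal penalty straightens
            # ties without changing the optimal move count
            ng = g[cell] + 1 + (1e-9 if dr and dc else 0.0)
            if ng < g.get(nb, math.inf):
                g[nb] = ng
                came[nb] = cell
                tie += 1
                heapq.heappush(open_heap, (ng + h(nb), tie, ng, nb))
    raise NoPathError(f"no navigable path from {start_cell} to {goal_cell}")


def _turn_of(prev_az: float, next_az: float) -> str:
    d = float(wrap_deg(next_az - prev_az))
    if abs(d) < 1.0:
        return "none"
    return "right" if d > 0 else "left"


def compute_path(
    grid: OccupancyGrid, start, goal, arrival_radius: float = 1.2
) -> GuidePath:
    """Plan a guide path across the grid from ``start`` to ``goal`` (world
    coordinates, meters).  The cell path is simplified to waypoints at
    direction changes; each interior waypoint carries a left/right turn
    annotation derived from the geometry."""
    start = np.asarray(start, dtype=float)
    goal = np.asarray(goal, dtype=float)
    for name, p in (("start", start), ("goal", goal)):
        if not grid.contains(p):
            raise NoPathError(f"{name} position {p[:2]} outside grid bounds")
    cells = astar_cells(grid, grid.cell_of(start), grid.cell_of(goal))

    # keep cells where the move direction changes
    keep = [0]
    for i in range(1, len(cells) - 1):
        d0 = (cells[i][0] - cells[i - 1][0], cells[i][1] - cells[i - 1][1])
        d1 = (cells[i + 1][0] - cells[i][0], cells[i + 1][1] - cells[i][1])
        if d0 != d1:
            keep.append(i)
    if len(cells) > 1:
        keep.append(len(cells) - 1)

    pts = [np.array([*grid.cell_center(cells[i]), 0.0]) for i in keep]
    if len(pts) < 2:
        # start and goal share a cell: degenerate straight segment
        a = np.array([start[0], start[1], 0.0])
        b = np.array([goal[0], goal[1], 0.0])
        if np.allclose(a, b):
            raise NoPathError("start and goal coincide")
        pts = [a, b]

    waypoints = []
    for i, p in enumerate(pts):
        turn = "none"
        if 0 < i < len(pts) - 1:
            a0 = absolute_azimuth(p[0] - pts[i - 1][0], p[1] - pts[i - 1][1])
            a1 = absolute_azimuth(pts[i + 1][0] - p[0], pts[i + 1][1] - p[1])
            turn = _turn_of(a0, a1)
        waypoints.append(Waypoint(position=p, turn=turn))
    return GuidePath(waypoints=tuple(waypoints), arrival_radius=arrival_radius)
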