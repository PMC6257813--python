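"""Executable task battery: localization, spatial memory, direct navigation,
guided navigation, and the three virtual-room benchmark tasks.

Simulation integrates agent motion at a fine substep (default 50 Hz) and
logs poses at 5 Hz, mirroring the head-tracking record.  Every run is fully
determined by the supplied RNG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .agent import (
    Action,
    AgentProfile,
    AimPolicy,
    DirectNavPolicy,
    GuideFollowPolicy,
    MemoryTrace,
    RandomSearchPolicy,
    RawScanPolicy,
    explore_and_store,
    recall,
)
from .angles import absolute_azimuth, heading_vector, wrap_deg
from .fixtures import (
    CHAIR_AZIMUTHS,
    MEMORY_AZIMUTHS,
    MEMORY_BLOCK_LABELS,
    arena_scene,
    building_path,
    chair_position,
    living_room_scene,
    memory_scene,
    position_at_azimuth,
)
from .guide import DEFAULT_GUIDE_PARAMS, GuideParams, GuideState, update_guide
from .scene import GuidePath, Pose, Scene, SceneObject, relative_azimuth
from .sonify import AudioEvent, spotlight_mode_events, target_mode_event, voice_encode

__all__ = [
    "TrialLog",
    "LocalizationConfig",
    "MemoryConfig",
    "DirectNavConfig",
    "GuidedNavConfig",
    "BenchmarkConfig",
    "run_localization_task",
    "run_memory_task",
    "run_direct_nav_task",
    "run_guided_nav_task",
    "run_benchmark_tasks",
    "render_view",
    "LOG_RATE_HZ",
    "SIM_RATE_HZ",
]

LOG_RATE_HZ = 5.0
SIM_RATE_HZ = 50.0


@dataclass
class TrialLog:
    """One trial: 5 Hz pose series, event stream, outcome and metadata."""

    task: str
    trial_index: int
    poses: np.ndarray  # (n, 7): t, x, y, z, yaw, pitch, roll
    events: List[AudioEvent]
    outcome: str  # completed | timeout | failed
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.poses[:, 0]

    @property
    def positions(self) -> np.ndarray:
        return self.poses[:, 1:4]

    @property
    def yaws(self) -> np.ndarray:
        return self.poses[:, 4]

    @property
    def duration(self) -> float:
        return float(self.poses[-1, 0] - self.poses[0, 0])


# ---------------------------------------------------------------------------
# Task configurations — defaults equal the published protocol values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalizationConfig:
    n_trials: int = 21
    target_distance: float = 1.0  # protocol value; some analyses quote 2 m
    time_limit: float = 120.0

    def __post_init__(self):
        if self.n_trials < 1 or self.target_distance <= 0 or self.time_limit <= 0:
            raise ValueError("invalid LocalizationConfig")


@dataclass(frozen=True)
class MemoryConfig:
    exploration_s: float = 60.0
    recalls_per_block: int = 4
    blocks: Tuple[int, ...] = (1, 2)
    target_distance: float = 2.0
    spotlight_aperture_deg: float = 30.0
    hold_s: float = 1.5  # dwell on the recalled direction before confirming

    def __post_init__(self):
        if self.exploration_s <= 0 or self.recalls_per_block < 1:
            raise ValueError("invalid MemoryConfig")


@dataclass(frozen=True)
class DirectNavConfig:
    n_trials: int = 20
    target_distance: float = 2.0
    completion_radius: float = 0.5
    start_zone_radius: float = 0.5  # 1 m diameter
    azimuths: Tuple[float, ...] = CHAIR_AZIMUTHS
    time_limit: float = 120.0
    baseline: bool = False  # cane-style search with audio off

    def __post_init__(self):
        if self.n_trials < 1 or self.completion_radius <= 0 or self.time_limit <= 0:
            raise ValueError("invalid DirectNavConfig")


@dataclass(frozen=True)
class GuidedNavConfig:
    time_limit: float = 300.0
    guide: GuideParams = DEFAULT_GUIDE_PARAMS

    def __post_init__(self):
        if self.time_limit <= 0:
            raise ValueError("invalid GuidedNavConfig")


@dataclass(frozen=True)
class BenchmarkConfig:
    n_trials: int = 20
    time_limit: float = 60.0
    max_consecutive_failures: int = 5
    key_distance_limit: float = 1.0
    key_angle_limit: float = 30.0
    chair_completion_radius: float = 0.5

    def __post_init__(self):
        if self.n_trials < 1 or self.time_limit <= 0:
            raise ValueError("invalid BenchmarkConfig")


# ---------------------------------------------------------------------------
# Simulation core
# ---------------------------------------------------------------------------


def _apply(pose: Pose, action: Action, t: float) -> Pose:
    yaw = float(wrap_deg(pose.yaw + action.dyaw))
    pos = pose.position
    if action.forward:
        pos = pos + np.array([*(heading_vector(yaw) * action.forward), 0.0])
    return Pose(t=t, position=pos, yaw=yaw, pitch=pose.pitch, roll=pose.roll)


def _simulate(
    policy,
    pose0: Pose,
    rng: np.random.Generator,
    time_limit: float,
    on_click: Optional[Callable[[Pose, float], List[AudioEvent]]] = None,
    is_complete: Optional[Callable[[Pose, float], bool]] = None,
    per_step: Optional[Callable[[Pose, float, float, list], None]] = None,
    transform_pose: Optional[Callable[[Pose], Pose]] = None,
    dt: float = 1.0 / SIM_RATE_HZ,
) -> Tuple[np.ndarray, List[AudioEvent], str, Pose]:
    """Generic trial loop.

    ``on_click`` supplies the audio response to a clicker press; every
    returned event is also fed to ``policy.hear``.  ``per_step`` lets task
    wrappers inject environment dynamics (e.g. the virtual guide); events it
    appends to its list argument are delivered to the policy as well.
    Completion is evaluated at the substep rate; poses are logged at 5 Hz
    plus one final sample at the exact end of the trial.
    """
    decim = max(1, int(round(1.0 / (LOG_RATE_HZ * dt))))
    pose = pose0
    rows = [pose.as_row()]
    events: List[AudioEvent] = []
    outcome = "timeout"
    n_steps = int(round(time_limit / dt))
    step = 0
    for step in range(1, n_steps + 1):
        t = step * dt
        if per_step is not None:
            injected: list = []
            per_step(pose, t, dt, injected)
            for ev in injected:
                events.append(ev)
                policy.hear(pose, ev, rng)
        action = policy.step(pose, dt, rng)
        if action.kind == "click":
            if on_click is not None:
                for ev in on_click(pose, t):
                    events.append(ev)
                    policy.hear(pose, ev, rng)
            pose = Pose(t=t, position=pose.position, yaw=pose.yaw, pitch=pose.pitch, roll=pose.roll)
        elif action.kind == "confirm":
            pose = Pose(t=t, position=pose.position, yaw=pose.yaw, pitch=pose.pitch, roll=pose.roll)
            outcome = "completed"
        else:
            pose = _apply(pose, action, t)
        if transform_pose is not None:
            pose = transform_pose(pose)
        done = outcome == "completed"
        if not done and is_complete is not None and is_complete(pose, t):
            outcome = "completed"
            done = True
        if step % decim == 0:
            rows.append(pose.as_row())
        if done:
            if step % decim != 0:
                rows.append(pose.as_row())
            break
    return np.array(rows), events, outcome, pose


# ---------------------------------------------------------------------------
# Task 1: object localization
# ---------------------------------------------------------------------------


def run_localization_task(
    profile: AgentProfile,
    config: LocalizationConfig = LocalizationConfig(),
    rng: Optional[np.random.Generator] = None,
) -> List[TrialLog]:
    """Aim-at-the-voice trials: a single target at a uniform random azimuth;
    the agent clicks, orients and confirms.  Logs the final aiming pose."""
    rng = np.random.default_rng(0) if rng is None else rng
    logs = []
    for trial in range(config.n_trials):
        target_az = float(rng.uniform(0.0, 360.0))
        target_pos = position_at_azimuth(target_az, config.target_distance)
        scene = Scene(
            objects=(SceneObject(id="box", label="box", position=target_pos, radius=0.3),),
            start_zone=None,
        )
        policy = AimPolicy(profile)
        pose0 = Pose(t=0.0, position=(0.0, 0.0, 0.0), yaw=0.0)

        def on_click(pose: Pose, t: float) -> List[AudioEvent]:
            return [target_mode_event(scene, pose, "box", t)]

        poses, events, outcome, final = _simulate(
            policy, pose0, rng, config.time_limit, on_click=on_click
        )
        logs.append(
            TrialLog(
                task="localization",
                trial_index=trial,
                poses=poses,
                events=events,
                outcome=outcome,
                meta={
                    "target_azimuth": float(wrap_deg(target_az)),
                    "target_position": target_pos.tolist(),
                    "aiming_error": float(relative_azimuth(final, target_pos)),
                },
            )
        )
    return logs


# ---------------------------------------------------------------------------
# Task 2: spatial memory
# ---------------------------------------------------------------------------


def _explore(
    scene: Scene,
    profile: AgentProfile,
    config: MemoryConfig,
    rng: np.random.Generator,
) -> Tuple[TrialLog, MemoryTrace]:
    """Spotlight exploration: sweep the head across the half circle for the
    exploration window, collecting name calls from the cone."""
    dt = 1.0 / LOG_RATE_HZ  # perception and logging both at 5 Hz here
    sweep_speed = profile.turn_speed / 2.0
    lo, hi = -75.0, 75.0
    yaw, direction = 0.0, 1.0
    rows, heard, events = [], [], []
    n = int(round(config.exploration_s * LOG_RATE_HZ))
    for i in range(n + 1):
        t = i * dt
        pose = Pose(t=t, position=(0.0, 0.0, 0.0), yaw=yaw)
        rows.append(pose.as_row())
        for ev in spotlight_mode_events(scene, pose, t, config.spotlight_aperture_deg):
            heard.append((pose, ev))
            events.append(ev)
        yaw += direction * sweep_speed * dt
        if yaw >= hi:
            yaw, direction = hi, -1.0
        elif yaw <= lo:
            yaw, direction = lo, 1.0
    trace = explore_and_store(scene, heard, profile, rng)
    log = TrialLog(
        task="memory-explore",
        trial_index=0,
        poses=np.array(rows),
        events=events,
        outcome="completed",
        meta={"n_objects": len(scene.objects)},
    )
    return log, trace


def run_memory_task(
    profile: AgentProfile,
    config: MemoryConfig = MemoryConfig(),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[TrialLog], List[TrialLog]]:
    """Exploration + recall blocks.  Returns (exploration logs, recall logs).

    The center object (azimuth 0, marked by sonar beeps) is never queried.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    explore_logs, recall_logs = [], []
    dt = 1.0 / SIM_RATE_HZ
    for block in config.blocks:
        scene = memory_scene(block, config.target_distance)
        explore_log, trace = _explore(scene, profile, config, rng)
        explore_log.trial_index = len(explore_logs)
        explore_log.meta["block"] = block
        explore_logs.append(explore_log)

        center_label = MEMORY_BLOCK_LABELS[block][MEMORY_AZIMUTHS.index(0.0)]
        candidates = [o for o in scene.objects if o.label != center_label]
        order = rng.permutation(len(candidates))[: config.recalls_per_block]
        for k, idx in enumerate(order):
            obj = candidates[int(idx)]
            recalled_az = recall(trace, obj.id, rng)
            true_az = absolute_azimuth(obj.position[0], obj.position[1])
            # open-loop turn to the recalled azimuth, hold, confirm
            rows = []
            yaw, t = 0.0, 0.0
            pose = Pose(t=t, position=(0.0, 0.0, 0.0), yaw=yaw)
            rows.append(pose.as_row())
            step = 0
            decim = int(round(SIM_RATE_HZ / LOG_RATE_HZ))
            hold = 0.0
            while hold < config.hold_s:
                step += 1
                t = step * dt
                err = float(wrap_deg(recalled_az - yaw))
                if abs(err) > 0.25:
                    yaw = float(wrap_deg(yaw + np.clip(err, -profile.turn_speed * dt, profile.turn_speed * dt)))
                else:
                    hold += dt
                pose = Pose(t=t, position=(0.0, 0.0, 0.0), yaw=yaw)
                if step % decim == 0:
                    rows.append(pose.as_row())
            if step % decim != 0:
                rows.append(pose.as_row())
            recall_logs.append(
                TrialLog(
                    task="memory-recall",
                    trial_index=len(recall_logs),
                    poses=np.array(rows),
                    events=[],
                    outcome="completed",
                    meta={
                        "block": block,
                        "object_id": obj.id,
                        "true_azimuth": float(true_az),
                        "recalled_azimuth": float(recalled_az),
                        "target_position": obj.position.tolist(),
                    },
                )
            )
    return explore_logs, recall_logs


# ---------------------------------------------------------------------------
# Task 3: direct navigation
# ---------------------------------------------------------------------------


def run_direct_nav_task(
    profile: AgentProfile,
    config: DirectNavConfig = DirectNavConfig(),
    rng: Optional[np.random.Generator] = None,
) -> List[TrialLog]:
    """Walk-to-the-voice trials from the central start zone to a chair at
    one of four azimuths.  With ``config.baseline`` the agent runs the
    uninformed search policy and receives no audio."""
    rng = np.random.default_rng(0) if rng is None else rng
    logs = []
    for trial in range(config.n_trials):
        az = float(config.azimuths[int(rng.integers(len(config.azimuths)))])
        scene = arena_scene(az, config.target_distance)
        chair = scene.object_by_id("chair")
        start_yaw = float(rng.uniform(-180.0, 180.0))
        pose0 = Pose(t=0.0, position=(0.0, 0.0, 0.0), yaw=start_yaw)

        if config.baseline:
            policy = RandomSearchPolicy(profile, arena_radius=4.0)
            on_click = None
        else:
            policy = DirectNavPolicy(profile)

            def on_click(pose: Pose, t: float, _scene=scene) -> List[AudioEvent]:
                return [target_mode_event(_scene, pose, "chair", t)]

        def is_complete(pose: Pose, t: float, _chair=chair) -> bool:
            return float(np.linalg.norm((pose.position - _chair.position)[:2])) <= config.completion_radius

        poses, events, outcome, _ = _simulate(
            policy, pose0, rng, config.time_limit, on_click=on_click, is_complete=is_complete
        )
        logs.append(
            TrialLog(
                task="direct-nav" + ("-baseline" if config.baseline else ""),
                trial_index=trial,
                poses=poses,
                events=events,
                outcome=outcome,
                meta={
                    "target_azimuth": az,
                    "target_position": chair.position.tolist(),
                    "completion_radius": config.completion_radius,
                    "baseline": config.baseline,
                },
            )
        )
    return logs


# ---------------------------------------------------------------------------
# Task 4: long-range guided navigation
# ---------------------------------------------------------------------------


def run_guided_nav_task(
    profile: AgentProfile,
    path: Optional[GuidePath] = None,
    config: GuidedNavConfig = GuidedNavConfig(),
    rng: Optional[np.random.Generator] = None,
) -> TrialLog:
    """Follow the virtual guide along the waypoint route until arrival or
    timeout.  The log carries segment boundaries (lobby/stairwell/hallway)
    and guide diagnostics (max along-path lead, call times)."""
    rng = np.random.default_rng(0) if rng is None else rng
    path = building_path() if path is None else path
    params = config.guide
    policy = GuideFollowPolicy(profile, guide_call_interval=params.call_interval)
    p0 = path.waypoints[0].position
    p1 = path.waypoints[1].position
    yaw0 = absolute_azimuth(p1[0] - p0[0], p1[1] - p0[1])
    pose0 = Pose(t=0.0, position=p0, yaw=yaw0)

    state = GuideState()
    cum = path.cumulative_lengths()
    diag = {"max_lead": -math.inf, "follow_me_times": [], "instruction_times": {}}
    crossing_times: Dict[int, float] = {}

    def per_step(pose: Pose, t: float, dt: float, out_events: list) -> None:
        nonlocal state
        state, evs = update_guide(state, path, pose.position, dt, t=t, params=params)
        lead = state.guide_s - state.user_s
        diag["max_lead"] = max(diag["max_lead"], lead)
        for i in range(1, len(cum)):
            if i not in crossing_times and state.user_s >= cum[i] - 1e-9:
                crossing_times[i] = t
        for ev in evs:
            if ev.kind == "follow_me":
                diag["follow_me_times"].append(ev.t)
            elif ev.kind == "instruction":
                diag["instruction_times"].setdefault(ev.label + f"@{len(diag['instruction_times'])}", ev.t)
            out_events.append(ev)

    def is_complete(pose: Pose, t: float) -> bool:
        return state.status == "arrived"

    height_s = {"s": 0.0}

    def sync_height(pose: Pose) -> Pose:
        # the subject climbs/descends with the route: snap z to the path
        # height at the current (monotone) projection
        s = path.project_monotone(pose.position, height_s["s"])
        height_s["s"] = s
        z = float(path.point_at(s)[2])
        if abs(z - pose.position[2]) < 1e-12:
            return pose
        return Pose(
            t=pose.t,
            position=np.array([pose.position[0], pose.position[1], z]),
            yaw=pose.yaw,
            pitch=pose.pitch,
            roll=pose.roll,
        )

    poses, events, outcome, _ = _simulate(
        policy, pose0, rng, config.time_limit, per_step=per_step,
        is_complete=is_complete, transform_pose=sync_height,
    )

    # segment boundaries from waypoint annotations
    seg_starts = [
        (i, w.segment) for i, w in enumerate(path.waypoints) if w.segment is not None
    ]
    segments = []
    t_end_total = float(poses[-1, 0])
    for k, (i, label) in enumerate(seg_starts):
        t_start = 0.0 if i == 0 else crossing_times.get(i, t_end_total)
        if k + 1 < len(seg_starts):
            j = seg_starts[k + 1][0]
            t_stop = crossing_times.get(j, t_end_total)
            l_ref = float(cum[j] - cum[i])
        else:
            t_stop = t_end_total
            l_ref = float(cum[-1] - cum[i])
        segments.append({"label": label, "t_start": t_start, "t_end": t_stop, "L_ref": l_ref})

    return TrialLog(
        task="guided-nav",
        trial_index=0,
        poses=poses,
        events=events,
        outcome=outcome,
        meta={
            "L_ref": path.length(),
            "segments": segments,
            "max_lead": diag["max_lead"],
            "follow_me_times": diag["follow_me_times"],
            "n_waypoints": len(path.waypoints),
            "arrival_radius": path.arrival_radius,
        },
    )


# ---------------------------------------------------------------------------
# Benchmark tasks in the virtual living room
# ---------------------------------------------------------------------------


def render_view(
    scene: Scene, pose: Pose, fov_deg: float = 120.0, shape: Tuple[int, int] = (24, 64)
) -> np.ndarray:
    """Crude grayscale rendering of the objects in view: column from
    azimuth, row from height, brightness falling with distance.  This is the
    reduced observation handed to the raw-sonification baseline."""
    rows, cols = shape
    img = np.zeros(shape)
    for o in scene.objects:
        rel = relative_azimuth(pose, o.position)
        if abs(rel) > fov_deg / 2:
            continue
        d = float(np.linalg.norm((o.position - pose.position)[:2]))
        col = int(round((rel / fov_deg + 0.5) * (cols - 1)))
        z = float(np.clip(o.position[2], 0.0, 2.0))
        row = int(round((1.0 - z / 2.0) * (rows - 1)))
        brightness = float(np.clip(o.radius / max(d, 0.3), 0.0, 1.0))
        r0, r1 = max(0, row - 1), min(rows, row + 2)
        c0, c1 = max(0, col - 1), min(cols, col + 2)
        img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], brightness)
    return img


def _benchmark_policy(profile: AgentProfile, sonifier: str, kind: str, config: BenchmarkConfig):
    if sonifier == "assistant":
        return AimPolicy(profile) if kind == "aim" else DirectNavPolicy(profile)
    if sonifier == "raw":
        # navigation trials complete geometrically, never by confirmation
        confirm_after = min(15.0, config.time_limit / 2) if kind == "aim" else math.inf
        return RawScanPolicy(profile, confirm_after=confirm_after)
    raise ValueError("sonifier must be 'assistant' or 'raw'")


def _run_benchmark_trial(
    scene: Scene,
    target: SceneObject,
    policy,
    sonifier: str,
    config: BenchmarkConfig,
    rng: np.random.Generator,
    is_complete,
    task_name: str,
    trial: int,
) -> TrialLog:
    pose0 = Pose(t=0.0, position=(0.0, 0.0, 0.0), yaw=float(rng.uniform(-180, 180)))

    if sonifier == "assistant":

        def on_click(pose: Pose, t: float) -> List[AudioEvent]:
            return [target_mode_event(scene, pose, target.id, t)]

    else:

        def on_click(pose: Pose, t: float) -> List[AudioEvent]:
            policy.observe(pose, voice_encode(render_view(scene, pose)), rng)
            return []

    poses, events, outcome, final = _simulate(
        policy, pose0, rng, config.time_limit, on_click=on_click, is_complete=is_complete
    )
    if outcome == "timeout":
        outcome = "failed"
    return TrialLog(
        task=task_name,
        trial_index=trial,
        poses=poses,
        events=events,
        outcome=outcome,
        meta={
            "sonifier": sonifier,
            "target_id": target.id,
            "target_position": target.position.tolist(),
            "aiming_error": float(relative_azimuth(final, target.position)),
        },
    )


def run_benchmark_tasks(
    profile: AgentProfile,
    scene: Optional[Scene] = None,
    sonifier: str = "assistant",
    config: BenchmarkConfig = BenchmarkConfig(),
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, List[TrialLog]]:
    """The three living-room benchmark tasks: aim at a random object,
    navigate to the chair, find the key on the floor.  Each task stops early
    after ``max_consecutive_failures`` failed trials in a row."""
    rng = np.random.default_rng(0) if rng is None else rng
    room = living_room_scene() if scene is None else scene
    results: Dict[str, List[TrialLog]] = {"aim": [], "nav-chair": [], "find-key": []}

    # --- task 1: scene understanding (aim at a named object) ---
    fails = 0
    for trial in range(config.n_trials):
        target = room.objects[int(rng.integers(len(room.objects)))]
        policy = _benchmark_policy(profile, sonifier, "aim", config)
        log = _run_benchmark_trial(
            room, target, policy, sonifier, config, rng, None, "benchmark-aim", trial
        )
        results["aim"].append(log)
        fails = fails + 1 if log.outcome == "failed" else 0
        if fails >= config.max_consecutive_failures:
            break

    # --- task 2: navigate to the chair ---
    fails = 0
    for trial in range(config.n_trials):
        az = float(CHAIR_AZIMUTHS[int(rng.integers(len(CHAIR_AZIMUTHS)))])
        chair_pos = chair_position(az)
        objects = tuple(
            SceneObject(id=o.id, label=o.label, position=chair_pos if o.id == "chair" else o.position, radius=o.radius)
            for o in room.objects
        )
        trial_scene = Scene(objects=objects, grid=room.grid, start_zone=room.start_zone)
        chair = trial_scene.object_by_id("chair")
        policy = _benchmark_policy(profile, sonifier, "nav", config)

        def is_complete(pose: Pose, t: float, _chair=chair) -> bool:
            return (
                float(np.linalg.norm((pose.position - _chair.position)[:2]))
                <= config.chair_completion_radius
            )

        log = _run_benchmark_trial(
            trial_scene, chair, policy, sonifier, config, rng, is_complete, "benchmark-nav", trial
        )
        results["nav-chair"].append(log)
        fails = fails + 1 if log.outcome == "failed" else 0
        if fails >= config.max_consecutive_failures:
            break

    # --- task 3: find the key (dual completion condition) ---
    fails = 0
    for trial in range(config.n_trials):
        key_az = float(rng.uniform(0.0, 360.0))
        key_dist = float(rng.uniform(1.5, 3.5))
        key = SceneObject(
            id="key", label="key", position=position_at_azimuth(key_az, key_dist, z=0.0), radius=0.05
        )
        trial_scene = Scene(objects=room.objects + (key,), grid=room.grid, start_zone=room.start_zone)
        policy = _benchmark_policy(profile, sonifier, "nav", config)

        def is_complete(pose: Pose, t: float, _key=key) -> bool:
            d = float(np.linalg.norm((pose.position - _key.position)[:2]))
            if d > config.key_distance_limit:
                return False
            if d < 1e-9:
                return True
            return abs(relative_azimuth(pose, _key.position)) <= config.key_angle_limit

        log = _run_benchmark_trial(
            trial_scene, key, policy, sonifier, config, rng, is_complete, "benchmark-key", trial
        )
        results["find-key"].append(log)
        fails = fails + 1 if log.outcome == "failed" else 0
        if fails >= config.max_consecutive_failures:
            break

    return results
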