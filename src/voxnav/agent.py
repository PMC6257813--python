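"""Stochastic user models: auditory localization, motor control policies,
and spatial memory.

Perception model: a sound's true relative azimuth is (rarely) mirrored
front-to-back about the interaural axis, then shifted by a systematic bias
and Gaussian noise.  All policies steer using such perceived azimuths plus
exact proprioception of their own yaw.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .angles import absolute_azimuth, heading_vector, mirror_front_back, wrap_deg
from .scene import Pose, Scene, relative_azimuth
from .sonify import AudioEvent

__all__ = [
    "AgentProfile",
    "MemoryTrace",
    "Action",
    "perceive_azimuth",
    "AimPolicy",
    "DirectNavPolicy",
    "GuideFollowPolicy",
    "RandomSearchPolicy",
    "RawScanPolicy",
    "explore_and_store",
    "recall",
    "BUILTIN_PROFILES",
]


@dataclass(frozen=True)
class AgentProfile:
    """Perceptual and motor parameters of one simulated user.

    Defaults are calibration values: bias/noise ranges follow the published
    per-subject localization spread, ``fb_confusion_prob`` the observed rate
    of wrong-direction starts (~5/139), and ``recall_noise_sd_deg`` the ~15
    degree rms recall accuracy.
    """

    bias_deg: float = 0.0
    noise_sd_deg: float = 0.0
    fb_confusion_prob: float = 0.0
    walk_speed: float = 1.2
    turn_speed: float = 90.0
    aim_tolerance_deg: float = 10.0
    click_interval: float = 0.5
    recall_noise_sd_deg: float = 0.0
    recovery_threshold_deg: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be >= 0")
        if not 0 <= self.fb_confusion_prob <= 1:
            raise ValueError("fb_confusion_prob must be in [0, 1]")
        if self.walk_speed <= 0 or self.turn_speed <= 0:
            raise ValueError("speeds must be > 0")
        if self.click_interval <= 0:
            raise ValueError("click_interval must be > 0")

    def to_json(self, path=None) -> dict:
        d = asdict(self)
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2, sort_keys=True)
                fh.write("\n")
        return d

    @classmethod
    def from_json(cls, source) -> "AgentProfile":
        if isinstance(source, dict):
            return cls(**source)
        with open(source) as fh:
            return cls(**json.load(fh))


BUILTIN_PROFILES: Dict[str, AgentProfile] = {
    "noiseless": AgentProfile(),
    "typical": AgentProfile(
        bias_deg=2.0, noise_sd_deg=7.0, fb_confusion_prob=0.036, recall_noise_sd_deg=15.0
    ),
    "noisy": AgentProfile(
        bias_deg=13.0, noise_sd_deg=12.0, fb_confusion_prob=0.036, recall_noise_sd_deg=15.0
    ),
}


def perceive_azimuth(true_az: float, profile: AgentProfile, rng: np.random.Generator) -> float:
    """Noisy perceived azimuth for a source at ``true_az`` degrees.

    With probability ``fb_confusion_prob`` the azimuth is first mirrored
    about the interaural axis; the systematic bias and Gaussian noise are
    then added and the result wrapped to (-180, 180].
    """
    az = float(true_az)
    if profile.fb_confusion_prob > 0 and rng.random() < profile.fb_confusion_prob:
        az = mirror_front_back(az)
    noise = rng.normal(0.0, profile.noise_sd_deg) if profile.noise_sd_deg > 0 else 0.0
    return float(wrap_deg(az + profile.bias_deg + noise))


@dataclass(frozen=True)
class Action:
    """One discrete step of agent output, applied by the task loop."""

    kind: str  # turn | walk | click | confirm | idle
    dyaw: float = 0.0     # degrees to rotate this step
    forward: float = 0.0  # meters to advance along the (new) heading


class _BasePolicy:
    """Shared plumbing: click scheduling and perceived-source bookkeeping."""

    def __init__(self, profile: AgentProfile):
        self.profile = profile
        self.believed_az_world: Optional[float] = None
        self.time_since_click = math.inf  # ready to click immediately

    def hear(self, pose: Pose, event: AudioEvent, rng: np.random.Generator) -> float:
        """Perceive an event and update the believed world azimuth of its
        source.  Returns the perceived relative azimuth."""
        true_rel = relative_azimuth(pose, event.source_position)
        perceived = perceive_azimuth(true_rel, self.profile, rng)
        self.believed_az_world = float(wrap_deg(pose.yaw + perceived))
        return perceived

    def _heading_error(self, pose: Pose) -> float:
        return float(wrap_deg(self.believed_az_world - pose.yaw))

    def _turn_step(self, err: float, dt: float) -> float:
        limit = self.profile.turn_speed * dt
        return float(np.clip(err, -limit, limit))


class AimPolicy(_BasePolicy):
    """Click, localize, turn to face the source, confirm.

    Confirms once the most recent perceived azimuth falls inside the aim
    tolerance, after completing the corresponding turn.
    """

    def __init__(self, profile: AgentProfile):
        super().__init__(profile)
        self.last_perceived: Optional[float] = None

    def hear(self, pose: Pose, event: AudioEvent, rng: np.random.Generator) -> float:
        self.last_perceived = super().hear(pose, event, rng)
        self.time_since_click = 0.0
        return self.last_perceived

    def step(self, pose: Pose, dt: float, rng: np.random.Generator) -> Action:
        self.time_since_click += dt
        if self.believed_az_world is None:
            return Action("click")
        err = self._heading_error(pose)
        if abs(err) > 0.25:  # still completing the turn toward the last call
            return Action("turn", dyaw=self._turn_step(err, dt))
        if abs(self.last_perceived) <= self.profile.aim_tolerance_deg:
            return Action("confirm")
        if self.time_since_click >= self.profile.click_interval:
            return Action("click")
        return Action("idle")


class DirectNavPolicy(_BasePolicy):
    """Two-phase controller: orient in place toward the voice, then walk
    swiftly toward it, re-clicking and correcting heading on the way.

    Re-enters the orient phase when a perceived azimuth exceeds the
    recovery threshold (models wrong-direction starts that get reversed).
    """

    def __init__(self, profile: AgentProfile):
        super().__init__(profile)
        self.phase = "orient"

    def hear(self, pose: Pose, event: AudioEvent, rng: np.random.Generator) -> float:
        perceived = super().hear(pose, event, rng)
        self.time_since_click = 0.0
        if self.phase == "walk" and abs(perceived) > self.profile.recovery_threshold_deg:
            self.phase = "orient"
        return perceived

    def step(self, pose: Pose, dt: float, rng: np.random.Generator) -> Action:
        self.time_since_click += dt
        if self.believed_az_world is None:
            return Action("click")
        err = self._heading_error(pose)
        if self.phase == "orient":
            if abs(err) > 0.25:
                return Action("turn", dyaw=self._turn_step(err, dt))
            if abs(err) <= self.profile.aim_tolerance_deg:
                self.phase = "walk"  # one-way transition per perception cycle
            elif self.time_since_click >= self.profile.click_interval:
                return Action("click")
            else:
                return Action("idle")
        # walk phase: steer while advancing
        if self.time_since_click >= self.profile.click_interval:
            return Action("click")
        dyaw = self._turn_step(err, dt)
        return Action("walk", dyaw=dyaw, forward=self.profile.walk_speed * dt)


class GuideFollowPolicy(_BasePolicy):
    """Walk toward the apparent location of the most recent "follow me"
    call (azimuth perceived with noise, distance from loudness/pitch);
    pause on arrival there and when the guide has gone quiet for more than
    twice its call interval."""

    def __init__(self, profile: AgentProfile, guide_call_interval: float = 2.0):
        super().__init__(profile)
        self.guide_call_interval = guide_call_interval
        self.time_since_event = math.inf
        self.believed_target: Optional[np.ndarray] = None

    def hear(self, pose: Pose, event: AudioEvent, rng: np.random.Generator) -> float:
        if event.kind != "follow_me":
            return 0.0
        self.time_since_event = 0.0
        perceived = super().hear(pose, event, rng)
        d = float(np.linalg.norm((event.source_position - pose.position)[:2]))
        direction = heading_vector(pose.yaw + perceived)
        self.believed_target = np.array(
            [*(pose.position[:2] + direction * d), event.source_position[2]]
        )
        return perceived

    def step(self, pose: Pose, dt: float, rng: np.random.Generator) -> Action:
        self.time_since_event += dt
        if self.believed_target is None or self.time_since_event > 2 * self.guide_call_interval:
            return Action("idle")
        to_target = self.believed_target[:2] - pose.position[:2]
        dist = float(np.linalg.norm(to_target))
        if dist < 0.15:
            return Action("idle")  # reached the last call; wait for the next
        err = float(wrap_deg(absolute_azimuth(to_target[0], to_target[1]) - pose.yaw))
        dyaw = self._turn_step(err, dt)
        if abs(err) > 90.0:
            return Action("turn", dyaw=dyaw)  # re-orient before walking
        forward = min(self.profile.walk_speed * dt, dist)
        return Action("walk", dyaw=dyaw, forward=forward)


class RandomSearchPolicy:
    """Uninformed search standing in for the cane-only baseline: a
    correlated random walk bounded to the arena.  Never consumes audio."""

    def __init__(self, profile: AgentProfile, arena_center=(0.0, 0.0), arena_radius: float = 4.0):
        self.profile = profile
        self.arena_center = np.asarray(arena_center, dtype=float)
        self.arena_radius = arena_radius
        self._wander_sd = 45.0  # deg/sqrt(s) heading diffusion

    def hear(self, pose: Pose, event: AudioEvent, rng: np.random.Generator) -> float:
        return 0.0  # audio off

    def step(self, pose: Pose, dt: float, rng: np.random.Generator) -> Action:
        offset = pose.position[:2] - self.arena_center
        if float(np.linalg.norm(offset)) > self.arena_radius:
            # turn back toward the arena center
            back = absolute_azimuth(-offset[0], -offset[1])
            err = float(wrap_deg(back - pose.yaw))
            limit = self.profile.turn_speed * dt
            return Action("turn", dyaw=float(np.clip(err, -limit, limit)))
        dyaw = float(rng.normal(0.0, self._wander_sd * math.sqrt(dt)))
        return Action("walk", dyaw=dyaw, forward=0.5 * self.profile.walk_speed * dt)


class RawScanPolicy:
    """Policy for the raw image-sonification baseline.

    The only observation is a spectrogram scan of the current view — no
    object identity — so the policy can merely steer toward the loudest
    (brightest) part of the soundscape and otherwise wander.  With many
    similar objects this yields near-chance task behavior by construction.
    """

    def __init__(self, profile: AgentProfile, fov_deg: float = 120.0, confirm_after: float = 15.0):
        self.profile = profile
        self.fov_deg = fov_deg
        self.confirm_after = confirm_after
        self.target_az_world: Optional[float] = None
        self.elapsed = 0.0
        self.time_since_scan = math.inf

    def observe(self, pose: Pose, scan, rng: np.random.Generator) -> None:
        """Digest a spectrogram scan: pick the brightest column and map its
        time position back to an azimuth inside the field of view."""
        self.time_since_scan = 0.0
        m = scan.matrix
        col_energy = m.sum(axis=0)
        if col_energy.sum() <= 0:
            self.target_az_world = float(wrap_deg(pose.yaw + rng.uniform(-90, 90)))
            return
        j = int(np.argmax(col_energy))
        frac = j / max(m.shape[1] - 1, 1)  # 0 = leftmost column
        rel = (frac - 0.5) * self.fov_deg
        self.target_az_world = float(wrap_deg(pose.yaw + rel))

    def step(self, pose: Pose, dt: float, rng: np.random.Generator) -> Action:
        self.elapsed += dt
        self.time_since_scan += dt
        if self.time_since_scan >= self.profile.click_interval:
            return Action("click")  # request a fresh scan
        if self.target_az_world is None:
            return Action("idle")
        if self.elapsed >= self.confirm_after:
            return Action("confirm")
        err = float(wrap_deg(self.target_az_world - pose.yaw))
        limit = self.profile.turn_speed * dt
        dyaw = float(np.clip(err, -limit, limit))
        if abs(err) > 20.0:
            return Action("turn", dyaw=dyaw)
        return Action("walk", dyaw=dyaw, forward=0.6 * self.profile.walk_speed * dt)


# ---------------------------------------------------------------------------
# Spatial memory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MemoryTrace:
    """Per-object remembered world azimuths formed during exploration."""

    azimuths: dict  # object id -> stored azimuth (deg, wrapped)
    recall_noise_sd_deg: float = 15.0


def explore_and_store(
    scene: Scene,
    heard: Iterable[Tuple[Pose, AudioEvent]],
    profile: AgentProfile,
    rng: np.random.Generator,
) -> MemoryTrace:
    """Build a memory trace from (pose, name-call event) pairs heard during
    exploration.  Each hearing contributes one noisy azimuth sample; the
    stored value is the circular mean over samples per object."""
    samples: Dict[str, list] = {}
    label_to_id = {o.label: o.id for o in scene.objects}
    pos_to_id = {tuple(np.round(o.position, 9)): o.id for o in scene.objects}
    for pose, event in heard:
        if event.kind != "name_call":
            continue
        oid = pos_to_id.get(tuple(np.round(event.source_position, 9)))
        if oid is None:
            oid = label_to_id.get(event.label)
        if oid is None:
            continue
        true_rel = relative_azimuth(pose, event.source_position)
        perceived = perceive_azimuth(true_rel, profile, rng)
        samples.setdefault(oid, []).append(float(wrap_deg(pose.yaw + perceived)))
    stored = {}
    for oid, vals in samples.items():
        rad = np.deg2rad(vals)
        stored[oid] = float(
            wrap_deg(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
        )
    return MemoryTrace(azimuths=stored, recall_noise_sd_deg=profile.recall_noise_sd_deg)


def recall(trace: MemoryTrace, object_id: str, rng: np.random.Generator) -> float:
    """Recalled azimuth of a stored object: stored value plus recall noise.
    Raises ``KeyError`` for an object never heard during exploration."""
    if object_id not in trace.azimuths:
        raise KeyError(f"object {object_id!r} not in memory trace")
    noise = rng.normal(0.0, trace.recall_noise_sd_deg) if trace.recall_noise_sd_deg > 0 else 0.0
    return float(wrap_deg(trace.azimuths[object_id] + noise))
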