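import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from voxnav.agent import (
    Action,
    AgentProfile,
    AimPolicy,
    DirectNavPolicy,
    GuideFollowPolicy,
    MemoryTrace,
    RandomSearchPolicy,
    explore_and_store,
    perceive_azimuth,
    recall,
)
from voxnav.fixtures import position_at_azimuth
from voxnav.scene import Pose, Scene, SceneObject
from voxnav.sonify import AudioEvent


class TestAgentProfile:
    def test_validation(self):
        with pytest.raises(ValueError):
            AgentProfile(noise_sd_deg=-1.0)
        with pytest.raises(ValueError):
            AgentProfile(fb_confusion_prob=1.5)
        with pytest.raises(ValueError):
            AgentProfile(walk_speed=0.0)

    def test_json_round_trip(self, tmp_path):
        prof = AgentProfile(bias_deg=5.0, noise_sd_deg=8.0, seed=42)
        path = tmp_path / "profile.json"
        prof.to_json(path)
        assert AgentProfile.from_json(path) == prof


class TestPerceiveAzimuth:
    def test_identity_when_noiseless(self, rng):
        prof = AgentProfile()
        assert perceive_azimuth(37.0, prof, rng) == pytest.approx(37.0)

    def test_pure_bias(self, rng):
        prof = AgentProfile(bias_deg=13.0)
        assert perceive_azimuth(0.0, prof, rng) == pytest.approx(13.0)

    def test_sd_recovered_monte_carlo(self):
        """Sample circular s.d. of 10^4 draws recovers the generating sd."""
        prof = AgentProfile(noise_sd_deg=10.0)
        rng = np.random.default_rng(0)
        draws = np.array([perceive_azimuth(0.0, prof, rng) for _ in range(10_000)])
        sd = float(stats.circstd(draws, high=180, low=-180))
        assert sd == pytest.approx(10.0, abs=0.5)

    def test_front_back_mirror(self):
        prof = AgentProfile(fb_confusion_prob=1.0)
        rng = np.random.default_rng(0)
        assert perceive_azimuth(30.0, prof, rng) == pytest.approx(150.0)
        assert perceive_azimuth(-10.0, prof, rng) == pytest.approx(-170.0)

    @given(az=st.floats(-180, 180), bias=st.floats(-30, 30), sd=st.floats(0, 30))
    @settings(max_examples=60)
    def test_output_in_range(self, az, bias, sd):
        prof = AgentProfile(bias_deg=bias, noise_sd_deg=sd, fb_confusion_prob=0.5)
        rng = np.random.default_rng(1)
        out = perceive_azimuth(az, prof, rng)
        assert -180.0 < out <= 180.0


def _run_policy_to_target(policy, target, profile, rng, max_t=60.0, dt=0.02):
    """Minimal closed loop: clicks answered by a call from the target."""
    pose = Pose(t=0.0, position=(0.0, 0.0, 0.0), yaw=0.0)
    trace = [pose.position[:2].copy()]
    t = 0.0
    while t < max_t:
        t += dt
        action = policy.step(pose, dt, rng)
        if action.kind == "click":
            ev = AudioEvent(t=t, kind="name_call", source_position=target, label="x")
            policy.hear(pose, ev, rng)
        elif action.kind == "confirm":
            break
        else:
            yaw = pose.yaw + action.dyaw
            newpos = pose.position.copy()
            if action.forward:
                r = np.deg2rad(yaw)
                newpos = newpos + action.forward * np.array([np.cos(r), -np.sin(r), 0.0])
            pose = Pose(t=t, position=newpos, yaw=yaw)
            trace.append(pose.position[:2].copy())
        if np.linalg.norm((pose.position - np.asarray(target))[:2]) < 0.5:
            break
    return pose, np.array(trace)


class TestDirectNavPolicy:
    def test_noiseless_straight_line(self):
        """Zero-noise agent: turn in place, then a straight walk."""
        prof = AgentProfile()
        rng = np.random.default_rng(0)
        target = position_at_azimuth(90.0, 2.0)
        pose, trace = _run_policy_to_target(DirectNavPolicy(prof), target, prof, rng)
        assert np.linalg.norm((pose.position - target)[:2]) < 0.5
        moving = trace[np.linalg.norm(np.diff(trace, axis=0, prepend=trace[:1]), axis=1) > 1e-9]
        if len(moving) > 2:
            # all displacement directions agree: straight line
            dirs = np.diff(moving, axis=0)
            dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
            assert float(np.min(dirs @ dirs[0])) > 0.999

    def test_full_confusion_walks_wrong_way(self):
        """fb_confusion 1 with the target behind: the agent hears it ahead
        and walks away from it."""
        prof = AgentProfile(fb_confusion_prob=1.0)
        rng = np.random.default_rng(0)
        target = np.array([-2.0, 0.0, 0.0])  # directly behind
        policy = DirectNavPolicy(prof)
        pose, trace = _run_policy_to_target(policy, target, prof, rng, max_t=2.0)
        d0 = 2.0
        d_end = float(np.linalg.norm((pose.position - target)[:2]))
        assert d_end > d0 + 0.5

    def test_intermittent_confusion_recovers(self):
        """Occasional mirroring produces a reversal, then the agent recovers
        and still reaches the target."""
        prof = AgentProfile(fb_confusion_prob=0.3, noise_sd_deg=3.0)
        rng = np.random.default_rng(3)
        target = np.array([-2.0, 0.0, 0.0])
        pose, trace = _run_policy_to_target(DirectNavPolicy(prof), target, prof, rng, max_t=60.0)
        assert np.linalg.norm((pose.position - target)[:2]) < 0.5

    def test_bias_gives_curved_approach(self):
        """A systematic bias yields a curved (spiral-like) approach that
        still converges."""
        prof = AgentProfile(bias_deg=-9.0, aim_tolerance_deg=5.0)
        rng = np.random.default_rng(1)
        target = position_at_azimuth(0.0, 2.0)
        pose, trace = _run_policy_to_target(DirectNavPolicy(prof), target, prof, rng)
        assert np.linalg.norm((pose.position - target)[:2]) < 0.5
        walked = float(np.linalg.norm(np.diff(trace, axis=0), axis=1).sum())
        assert walked > 1.5  # longer than the 2.0 - 0.5 straight line


class TestGuideFollowPolicy:
    def test_pauses_when_guide_silent(self):
        prof = AgentProfile()
        policy = GuideFollowPolicy(prof, guide_call_interval=2.0)
        rng = np.random.default_rng(0)
        pose = Pose(t=0, position=(0, 0, 0), yaw=0.0)
        ev = AudioEvent(t=0, kind="follow_me", source_position=(1.0, 0, 0), label="follow me")
        policy.hear(pose, ev, rng)
        # silence for > 2 call intervals: policy goes idle
        for _ in range(300):
            action = policy.step(pose, 0.02, rng)
        assert action.kind == "idle"

    def test_walks_toward_call(self):
        prof = AgentProfile()
        policy = GuideFollowPolicy(prof)
        rng = np.random.default_rng(0)
        pose = Pose(t=0, position=(0, 0, 0), yaw=0.0)
        policy.hear(pose, AudioEvent(t=0, kind="follow_me", source_position=(1.0, 0, 0)), rng)
        action = policy.step(pose, 0.02, rng)
        assert action.kind == "walk" and action.forward > 0

    def test_ignores_other_kinds(self):
        prof = AgentProfile()
        policy = GuideFollowPolicy(prof)
        rng = np.random.default_rng(0)
        pose = Pose(t=0, position=(0, 0, 0), yaw=0.0)
        policy.hear(pose, AudioEvent(t=0, kind="instruction", source_position=(1, 0, 0)), rng)
        assert policy.believed_target is None


class TestRandomSearch:
    def test_never_uses_audio(self):
        prof = AgentProfile()
        policy = RandomSearchPolicy(prof)
        rng = np.random.default_rng(0)
        pose = Pose(t=0, position=(0, 0, 0), yaw=0.0)
        policy.hear(pose, AudioEvent(t=0, kind="name_call", source_position=(1, 0, 0)), rng)
        # hearing changes nothing; the walk is a bounded random wander
        positions = []
        for _ in range(2000):
            action = policy.step(pose, 0.02, rng)
            yaw = pose.yaw + action.dyaw
            newpos = pose.position.copy()
            if action.forward:
                r = np.deg2rad(yaw)
                newpos = newpos + action.forward * np.array([np.cos(r), -np.sin(r), 0.0])
            pose = Pose(t=0, position=newpos, yaw=yaw)
            positions.append(newpos[:2].copy())
        positions = np.array(positions)
        assert np.linalg.norm(positions, axis=1).max() < 5.5  # stays near the arena


class TestMemory:
    def _scene(self):
        return Scene(
            objects=tuple(
                SceneObject(id=f"o{i}", label=f"o{i}", position=position_at_azimuth(az, 2.0))
                for i, az in enumerate([-60, 0, 60])
            )
        )

    def _heard(self, scene):
        pose = Pose(t=0, position=(0, 0, 0), yaw=0.0)
        return [
            (pose, AudioEvent(t=0, kind="name_call", source_position=o.position, label=o.label))
            for o in scene.objects
        ]

    def test_zero_noise_exact_recall(self, rng):
        scene = self._scene()
        trace = explore_and_store(scene, self._heard(scene), AgentProfile(), rng)
        for oid, az in [("o0", -60.0), ("o1", 0.0), ("o2", 60.0)]:
            assert recall(trace, oid, rng) == pytest.approx(az, abs=1e-9)

    def test_recall_noise_rms(self):
        rng = np.random.default_rng(0)
        scene = self._scene()
        trace = explore_and_store(scene, self._heard(scene), AgentProfile(), rng)
        trace = MemoryTrace(azimuths=trace.azimuths, recall_noise_sd_deg=15.0)
        errs = [recall(trace, "o1", rng) for _ in range(2000)]
        assert float(np.std(errs)) == pytest.approx(15.0, abs=1.0)

    def test_unseen_object_raises(self, rng):
        scene = self._scene()
        trace = explore_and_store(scene, self._heard(scene), AgentProfile(), rng)
        with pytest.raises(KeyError):
            recall(trace, "ghost", rng)
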