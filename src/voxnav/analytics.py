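"""Trajectory and aiming analytics: smoothing, deviation index, phase
segmentation, speeds, circular statistics and summary tables.

The deviation index DI = (L_exp - L_ref) / L_ref measures the fractional
excess of the walked path over a reference path; values near 0 indicate
faithful following, negative values corner cutting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .angles import wrap_deg
from .scene import Pose, relative_azimuth
from .tasks import TrialLog

__all__ = [
    "TrajectoryMetrics",
    "AimingResult",
    "smooth",
    "path_length",
    "deviation_index",
    "segment_phases",
    "walking_speed",
    "aiming_error_at",
    "aiming_stats",
    "recover_profile_params",
    "recall_regression",
    "rayleigh_test",
    "direct_nav_metrics",
    "guided_segment_metrics",
    "summarize",
]


@dataclass(frozen=True)
class TrajectoryMetrics:
    L_exp: float
    L_ref: float
    DI: float
    speed_p90: float
    normalized_speed: float
    duration: float

    def __post_init__(self):
        if self.L_exp < 0:
            raise ValueError("L_exp must be >= 0")


@dataclass(frozen=True)
class AimingResult:
    """Signed per-trial aiming errors with their circular summary stats."""

    errors: np.ndarray  # degrees, wrapped to (-180, 180]
    bias: float         # circular mean
    accuracy: float     # circular s.d.


# ---------------------------------------------------------------------------
# Trajectory processing
# ---------------------------------------------------------------------------


def smooth(series: np.ndarray, window_s: float = 2.0, rate_hz: float = 5.0) -> np.ndarray:
    """Centered moving average over a ``window_s``-second sliding window.

    The nominal window is ``round(window_s * rate_hz)`` samples, widened to
    the next odd count so it can be truly centered (a centered average of an
    affine series then reproduces it exactly in the interior).  Edges use a
    symmetric shrinking window so length and both endpoints are preserved.
    ``series`` is an (n, k) array (or (n,) vector); columns are averaged
    independently — apply to positions, not wrapped angles.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot smooth an empty series")
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    n = arr.shape[0]
    w = max(1, int(round(window_s * rate_hz)))
    half = w // 2
    out = np.empty_like(arr)
    csum = np.vstack([np.zeros((1, arr.shape[1])), np.cumsum(arr, axis=0)])
    for i in range(n):
        h = min(half, i, n - 1 - i)  # symmetric, shrinking at the edges
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out[:, 0] if squeeze else out


def smooth_log_positions(log: TrialLog, window_s: float = 2.0) -> np.ndarray:
    """Smoothed (n, 3) positions of a trial log at its native 5 Hz rate."""
    t = log.times
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 5.0
    return smooth(log.positions, window_s=window_s, rate_hz=rate)


def path_length(series: np.ndarray) -> float:
    """Sum of successive displacement norms over an (n, d) position series."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(arr, axis=0), axis=1).sum())


def deviation_index(L_exp: float, L_ref: float) -> float:
    """(L_exp - L_ref) / L_ref; negative when the reference is undercut."""
    if L_ref <= 0:
        raise ValueError("L_ref must be > 0")
    return (L_exp - L_ref) / L_ref


def segment_phases(
    positions: np.ndarray, target_position, threshold: float = 0.3
) -> Optional[int]:
    """Index of the navigation-phase onset: the first sample where the 2D
    distance to target has changed by ``threshold`` meters in either
    direction (wrong-direction starts count).  None if never reached."""
    pos = np.asarray(positions, dtype=float)[:, :2]
    tgt = np.asarray(target_position, dtype=float)[:2]
    d = np.linalg.norm(pos - tgt, axis=1)
    moved = np.abs(d - d[0]) >= threshold
    idx = np.nonzero(moved)[0]
    return int(idx[0]) if idx.size else None


def walking_speed(
    positions: np.ndarray,
    times: np.ndarray,
    free_walk_speed: float = 1.2,
    use_3d: bool = False,
) -> Tuple[float, float]:
    """(90th-percentile speed, speed normalized by free walking speed).

    Frame-wise displacement over dt on an already-smoothed series; the 90th
    percentile robustly rejects stationary orientation phases.  3D
    displacement is used for routes with vertical motion, 2D otherwise.
    """
    if free_walk_speed <= 0:
        raise ValueError("free_walk_speed must be > 0")
    pos = np.asarray(positions, dtype=float)
    pos = pos[:, :3] if use_3d else pos[:, :2]
    t = np.asarray(times, dtype=float)
    if len(t) < 2:
        return 0.0, 0.0
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dts = np.diff(t)
    speeds = disp / dts
    p90 = float(np.percentile(speeds, 90))
    return p90, p90 / free_walk_speed


# ---------------------------------------------------------------------------
# Aiming statistics (circular)
# ---------------------------------------------------------------------------


def aiming_error_at(log: TrialLog, offset_before_end: float = 0.0) -> float:
    """Signed aiming error (target azimuth minus facing azimuth) measured
    ``offset_before_end`` seconds before the end of the trial."""
    target = np.asarray(log.meta["target_position"], dtype=float)
    t_eval = log.times[-1] - offset_before_end
    i = int(np.searchsorted(log.times, t_eval, side="right") - 1)
    i = max(i, 0)
    row = log.poses[i]
    pose = Pose(t=row[0], position=row[1:4], yaw=row[4])
    return float(relative_azimuth(pose, target))


def aiming_stats(
    trials: Sequence[TrialLog], offset_before_end: float = 0.0
) -> AimingResult:
    """Circular bias (mean) and accuracy (s.d.) of per-trial aiming errors."""
    errors = np.array([aiming_error_at(log, offset_before_end) for log in trials])
    return _aiming_from_errors(errors)


def _aiming_from_errors(errors: np.ndarray) -> AimingResult:
    errors = wrap_deg(np.asarray(errors, dtype=float))
    bias = float(stats.circmean(errors, high=180.0, low=-180.0))
    accuracy = float(stats.circstd(errors, high=180.0, low=-180.0))
    return AimingResult(errors=errors, bias=float(wrap_deg(bias)), accuracy=accuracy)


def _gate_shrink(ratio: float, n_paths: int = 20000, max_iter: int = 200) -> float:
    """Std of the final accepted noise draw, in units of the generating sd,
    for the aim-and-confirm loop with tolerance/sd ratio ``ratio``.

    The confirm gate accepts the trial when consecutive percepts agree
    within the tolerance, which truncates the retained noise draw; this
    Monte Carlo of the scalar accept recursion quantifies that shrinkage.
    Deterministic (fixed internal seed).
    """
    rng = np.random.default_rng(987654321)
    prev = rng.standard_normal(n_paths)
    out = np.empty(n_paths)
    active = np.ones(n_paths, dtype=bool)
    for _ in range(max_iter):
        cur = rng.standard_normal(n_paths)
        acc = active & (np.abs(cur - prev) <= ratio)
        out[acc] = cur[acc]  # the accepted percept's noise is what remains
        active &= ~acc
        if not active.any():
            break
        prev = cur
    out[active] = prev[active]
    return float(out.std())


def recover_profile_params(
    result: AimingResult, aim_tolerance_deg: float = 10.0, gate_corrected: bool = True
) -> Tuple[float, float]:
    """Estimate (bias_deg, noise_sd_deg) of the generating profile from
    closed-loop aiming errors.

    Turning *toward* a positively-biased percept leaves the head offset to
    the opposite side, so the perceptual bias is minus the observed aiming
    bias.  The observed accuracy understates the perceptual noise because
    the agent only confirms when the latest percept clears the aim
    tolerance; with ``gate_corrected`` the estimator inverts that known
    selection effect.
    """
    bias = -result.bias
    sd_obs = result.accuracy
    if not gate_corrected or sd_obs <= 0:
        return bias, sd_obs
    lo, hi = sd_obs, 4.0 * sd_obs + 1.0
    for _ in range(40):  # bisection: sd * shrink(tol/sd) is increasing in sd
        mid = 0.5 * (lo + hi)
        if mid * _gate_shrink(aim_tolerance_deg / mid) < sd_obs:
            lo = mid
        else:
            hi = mid
    return bias, 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Regression and circular uniformity
# ---------------------------------------------------------------------------


def recall_regression(
    true_angles: Sequence[float], recalled_angles: Sequence[float]
) -> Tuple[float, float, float]:
    """OLS of recalled on true angles: (slope, intercept, r)."""
    x = np.asarray(true_angles, dtype=float)
    y = np.asarray(recalled_angles, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired angles")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def rayleigh_test(angles_deg: Sequence[float]) -> Tuple[float, float]:
    """Rayleigh z test of circular uniformity.

    Returns (z, p) with z = n * Rbar**2 and the standard series
    approximation for p, accurate for moderate n.  Requires n >= 2.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    rbar = float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))
    z = n * rbar**2
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(z), float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Per-task metric pipelines
# ---------------------------------------------------------------------------


def direct_nav_metrics(
    log: TrialLog,
    free_walk_speed: float = 1.2,
    phase_threshold: float = 0.3,
    window_s: float = 2.0,
) -> TrajectoryMetrics:
    """Metrics for one direct-navigation trial.

    L_ref is the straight line from the navigation-phase onset to the
    nearest point of the target trigger zone; L_exp the smoothed trajectory
    length from that onset.
    """
    target = np.asarray(log.meta["target_position"], dtype=float)
    radius = float(log.meta.get("completion_radius", 0.5))
    smoothed = smooth_log_positions(log, window_s)
    onset = segment_phases(smoothed, target, phase_threshold)
    if onset is None:
        onset = 0
    seg = smoothed[onset:, :2]
    l_exp = path_length(seg)
    d0 = float(np.linalg.norm(smoothed[onset, :2] - target[:2]))
    l_ref = max(d0 - radius, 1e-9)
    p90, norm = walking_speed(smoothed[onset:], log.times[onset:], free_walk_speed, use_3d=False)
    return TrajectoryMetrics(
        L_exp=l_exp,
        L_ref=l_ref,
        DI=deviation_index(l_exp, l_ref),
        speed_p90=p90,
        normalized_speed=norm,
        duration=log.duration,
    )


def guided_segment_metrics(
    log: TrialLog, free_walk_speed: float = 1.2, window_s: float = 2.0
) -> List[Tuple[str, TrajectoryMetrics]]:
    """(segment label, metrics) pairs for a guided-navigation log, plus an
    'overall' entry.  Speeds use 3D displacement (stairs)."""
    smoothed = smooth_log_positions(log, window_s)
    t = log.times
    out = []
    entries = list(log.meta.get("segments", [])) + [
        {"label": "overall", "t_start": float(t[0]), "t_end": float(t[-1]), "L_ref": float(log.meta["L_ref"])}
    ]
    for segd in entries:
        sel = (t >= segd["t_start"] - 1e-9) & (t <= segd["t_end"] + 1e-9)
        pos = smoothed[sel]
        tt = t[sel]
        if pos.shape[0] < 2:
            continue
        l_exp = path_length(pos)
        l_ref = float(segd["L_ref"])
        p90, norm = walking_speed(pos, tt, free_walk_speed, use_3d=True)
        out.append(
            (
                segd["label"],
                TrajectoryMetrics(
                    L_exp=l_exp,
                    L_ref=l_ref,
                    DI=deviation_index(l_exp, l_ref),
                    speed_p90=p90,
                    normalized_speed=norm,
                    duration=float(tt[-1] - tt[0]),
                ),
            )
        )
    return out


def summarize(
    logs: Iterable[TrialLog], free_walk_speed: float = 1.2, profile: str = ""
) -> pd.DataFrame:
    """Tidy metric table: one row per trial (per segment for guided runs).

    Columns: task, profile, trial, segment, outcome, duration, L_exp,
    L_ref, DI, speed_p90, normalized_speed, aiming_error.
    """
    rows = []
    for log in logs:
        base = {
            "task": log.task,
            "profile": profile,
            "trial": log.trial_index,
            "segment": "",
            "outcome": log.outcome,
            "duration": log.duration,
            "L_exp": np.nan,
            "L_ref": np.nan,
            "DI": np.nan,
            "speed_p90": np.nan,
            "normalized_speed": np.nan,
            "aiming_error": np.nan,
        }
        if log.task.startswith("direct-nav") or log.task == "benchmark-nav":
            try:
                m = direct_nav_metrics(log, free_walk_speed)
                base.update(
                    L_exp=m.L_exp, L_ref=m.L_ref, DI=m.DI,
                    speed_p90=m.speed_p90, normalized_speed=m.normalized_speed,
                )
            except (KeyError, ValueError):
                pass
            rows.append(base)
        elif log.task == "guided-nav":
            for label, m in guided_segment_metrics(log, free_walk_speed):
                row = dict(base)
                row.update(
                    segment=label, L_exp=m.L_exp, L_ref=m.L_ref, DI=m.DI,
                    speed_p90=m.speed_p90, normalized_speed=m.normalized_speed,
                    duration=m.duration,
                )
                rows.append(row)
        else:
            offset = 1.0 if log.task == "memory-recall" else 0.0
            if "target_position" in log.meta:
                try:
                    base["aiming_error"] = aiming_error_at(log, offset)
                except Exception:
                    pass
            rows.append(base)
    columns = [
        "task", "profile", "trial", "segment", "outcome", "duration",
        "L_exp", "L_ref", "DI", "speed_p90", "normalized_speed", "aiming_error",
    ]
    return pd.DataFrame(rows, columns=columns)
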