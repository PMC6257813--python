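"""Audio event generation: talking-object modes, collision warning, and the
raw image-to-spectrogram sonification baseline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .scene import (
    Pose,
    Scene,
    in_spotlight,
    nearest_obstacle_point,
    relative_azimuth,
    scan_order,
)

__all__ = [
    "AudioEvent",
    "PitchMap",
    "SpectrogramScan",
    "EVENT_KINDS",
    "pitch_for_distance",
    "target_mode_event",
    "spotlight_mode_events",
    "scan_mode_events",
    "collision_warning",
    "voice_encode",
    "synthesize_waveform",
    "write_wav",
]

EVENT_KINDS = ("name_call", "follow_me", "hiss", "instruction", "feedback")

#: floor used when computing pitch for zero distance
_EPS_DISTANCE = 1e-6


@dataclass(frozen=True)
class AudioEvent:
    """One sonification emission with its apparent source location."""

    t: float
    kind: str
    source_position: np.ndarray
    label: str = ""
    pitch_factor: float = 1.0

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")
        object.__setattr__(
            self, "source_position", np.asarray(self.source_position, dtype=float)
        )
        if not math.isfinite(self.pitch_factor) or self.pitch_factor < 0:
            raise ValueError("pitch_factor must be finite and >= 0")

    def to_dict(self) -> dict:
        return {
            "t": float(self.t),
            "kind": self.kind,
            "source_position": [float(v) for v in self.source_position],
            "label": self.label,
            "pitch_factor": float(self.pitch_factor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AudioEvent":
        return cls(
            t=d["t"],
            kind=d["kind"],
            source_position=d["source_position"],
            label=d.get("label", ""),
            pitch_factor=d.get("pitch_factor", 1.0),
        )


@dataclass(frozen=True)
class PitchMap:
    """Distance-to-pitch mapping: pitch rises as the object gets closer.

    ``pitch_for_distance`` evaluates ``min(max_factor, d_ref / d)`` so the
    factor equals 1 at the reference distance and saturates at
    ``max_factor`` near the head.
    """

    d_ref: float = 2.0
    max_factor: float = 4.0

    def __post_init__(self):
        if not self.d_ref > 0:
            raise ValueError("d_ref must be > 0")
        if not self.max_factor >= 1:
            raise ValueError("max_factor must be >= 1")


DEFAULT_PITCH_MAP = PitchMap()


def pitch_for_distance(d: float, pitch_map: PitchMap = DEFAULT_PITCH_MAP) -> float:
    """Pitch multiplier for a source at distance ``d`` (meters)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return float(min(pitch_map.max_factor, pitch_map.d_ref / max(d, _EPS_DISTANCE)))


def target_mode_event(
    scene: Scene,
    pose: Pose,
    target_id: str,
    t: float,
    pitch_map: PitchMap = DEFAULT_PITCH_MAP,
) -> AudioEvent:
    """Name call from the selected object (one emission per clicker press)."""
    obj = scene.object_by_id(target_id)
    d = float(np.linalg.norm(obj.position - pose.position))
    return AudioEvent(
        t=t,
        kind="name_call",
        source_position=obj.position,
        label=obj.label,
        pitch_factor=pitch_for_distance(d, pitch_map),
    )


def spotlight_mode_events(
    scene: Scene,
    pose: Pose,
    t: float,
    aperture_deg: float = 30.0,
    pitch_map: PitchMap = DEFAULT_PITCH_MAP,
) -> List[AudioEvent]:
    """Name calls for every object inside the facing cone, nearest first."""
    hits = [
        o for o in scene.objects if in_spotlight(pose, o.position, aperture_deg)
    ]
    hits.sort(key=lambda o: (float(np.linalg.norm(o.position - pose.position)), o.id))
    return [
        AudioEvent(
            t=t,
            kind="name_call",
            source_position=o.position,
            label=o.label,
            pitch_factor=pitch_for_distance(
                float(np.linalg.norm(o.position - pose.position)), pitch_map
            ),
        )
        for o in hits
    ]


def scan_mode_events(
    scene: Scene,
    pose: Pose,
    t: float,
    inter_call_gap: float = 1.0,
    pitch_map: PitchMap = DEFAULT_PITCH_MAP,
) -> List[AudioEvent]:
    """Left-to-right roll call of the whole scene, one call per gap."""
    events = []
    for k, o in enumerate(scan_order(scene, pose)):
        d = float(np.linalg.norm(o.position - pose.position))
        events.append(
            AudioEvent(
                t=t + k * inter_call_gap,
                kind="name_call",
                source_position=o.position,
                label=o.label,
                pitch_factor=pitch_for_distance(d, pitch_map),
            )
        )
    return events


def collision_warning(
    scene: Scene, pose: Pose, t: float, warn_dist: float = 0.7
) -> Optional[AudioEvent]:
    """Hiss from the nearest surface when closer than ``warn_dist`` (strict)."""
    d, point = nearest_obstacle_point(scene, pose.position)
    if point is None or d >= warn_dist:
        return None
    return AudioEvent(t=t, kind="hiss", source_position=point, label="hiss")


# ---------------------------------------------------------------------------
# Raw sensory-substitution baseline: image interpreted as a spectrogram,
# scanned left to right (brightness -> loudness, height -> pitch).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrogramScan:
    """Image-as-spectrogram: rows are frequency bins (top row = highest
    frequency), columns are time steps (left column = first)."""

    matrix: np.ndarray
    scan_duration: float = 1.0
    freq_range: tuple = (500.0, 5000.0)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("matrix must be a non-empty 2D array")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("matrix values must lie in [0, 1]")
        if not self.scan_duration > 0:
            raise ValueError("scan_duration must be > 0")
        lo, hi = self.freq_range
        if not (0 < lo < hi):
            raise ValueError("freq_range must be an increasing positive pair")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "freq_range", (float(lo), float(hi)))

    @property
    def frequencies(self) -> np.ndarray:
        """Per-row frequency (Hz), logarithmically spaced, descending from
        the top row."""
        lo, hi = self.freq_range
        n = self.matrix.shape[0]
        if n == 1:
            return np.array([hi])
        return np.geomspace(hi, lo, n)

    @property
    def times(self) -> np.ndarray:
        """Per-column onset time (s); column j plays at j/(cols-1)*duration."""
        n = self.matrix.shape[1]
        if n == 1:
            return np.array([0.0])
        return np.arange(n) / (n - 1) * self.scan_duration


def voice_encode(
    image: np.ndarray,
    scan_duration: float = 1.0,
    freq_range: tuple = (500.0, 5000.0),
) -> SpectrogramScan:
    """Encode a grayscale image (values in [0, 1], row 0 = top) as a
    left-to-right spectrogram scan.  Amplitude equals brightness, so the
    encoding is linear in the image."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return SpectrogramScan(matrix=img.copy(), scan_duration=scan_duration, freq_range=freq_range)


def synthesize_waveform(scan: SpectrogramScan, sample_rate: int = 22050) -> np.ndarray:
    """Render a scan to a mono waveform by summing amplitude-weighted
    sinusoids column by column.  Peak-normalized to <= 1."""
    n_rows, n_cols = scan.matrix.shape
    col_samples = max(1, int(round(scan.scan_duration * sample_rate / n_cols)))
    freqs = scan.frequencies
    out = np.zeros(col_samples * n_cols)
    tt = np.arange(col_samples) / sample_rate
    for j in range(n_cols):
        col = scan.matrix[:, j]
        active = np.nonzero(col)[0]
        if active.size == 0:
            continue
        t0 = j * col_samples / sample_rate
        seg = np.zeros(col_samples)
        for i in active:
            seg += col[i] * np.sin(2 * np.pi * freqs[i] * (t0 + tt))
        out[j * col_samples : (j + 1) * col_samples] = seg
    peak = np.abs(out).max()
    if peak > 1.0:
        out /= peak
    return out


def write_wav(path, waveform: np.ndarray, sample_rate: int = 22050) -> None:
    """Write a mono float waveform to a 16-bit WAV file."""
    from scipy.io import wavfile

    data = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, sample_rate, (data * 32767).astype(np.int16))
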