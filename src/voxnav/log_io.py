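"""Trial log persistence: 5 Hz pose CSV plus JSON-lines event sidecar and a
JSON metadata file per trial."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import numpy as np

from .sonify import AudioEvent
from .tasks import TrialLog

__all__ = ["write_trial_log", "read_trial_log", "write_logs", "read_logs"]

_POSE_HEADER = "t,x,y,z,yaw,pitch,roll"


def _stem(log: TrialLog) -> str:
    return f"{log.task}_{log.trial_index:03d}"


def write_trial_log(log: TrialLog, out_dir) -> Path:
    """Write <task>_<idx>.csv / .events.jsonl / .meta.json; returns the CSV
    path.  Numeric formatting is fixed so identical runs are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = _stem(log)
    csv_path = out / f"{stem}.csv"
    with open(csv_path, "w") as fh:
        fh.write(_POSE_HEADER + "\n")
        for row in log.poses:
            fh.write(",".join(f"{v:.6f}" for v in row) + "\n")
    with open(out / f"{stem}.events.jsonl", "w") as fh:
        for ev in log.events:
            fh.write(json.dumps(ev.to_dict(), sort_keys=True) + "\n")
    meta = {"task": log.task, "trial_index": log.trial_index, "outcome": log.outcome}
    meta.update(_jsonable(log.meta))
    with open(out / f"{stem}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj in (float("inf"), float("-inf")):
        return None
    return obj


def read_trial_log(csv_path) -> TrialLog:
    csv_path = Path(csv_path)
    stem = csv_path.name[: -len(".csv")]
    poses = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    events: List[AudioEvent] = []
    events_path = csv_path.with_name(stem + ".events.jsonl")
    if events_path.exists():
        with open(events_path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    events.append(AudioEvent.from_dict(json.loads(line)))
    meta_path = csv_path.with_name(stem + ".meta.json")
    meta: dict = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    task = meta.pop("task", stem.rsplit("_", 1)[0])
    trial_index = meta.pop("trial_index", 0)
    outcome = meta.pop("outcome", "completed")
    return TrialLog(
        task=task, trial_index=int(trial_index), poses=poses,
        events=events, outcome=outcome, meta=meta,
    )


def write_logs(logs, out_dir) -> List[Path]:
    return [write_trial_log(log, out_dir) for log in logs]


def read_logs(log_dir) -> List[TrialLog]:
    """Read every trial log in a directory, sorted by file name."""
    paths = sorted(p for p in Path(log_dir).glob("*.csv"))
    return [read_trial_log(p) for p in paths]
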