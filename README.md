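# voxnav

A hardware-free, desk-scale simulator and analysis toolkit for
spatialized-audio navigation assistants for the blind. It models an
augmented-audio interface in which every object in a scene can "talk" from
its location (scan / spotlight / target modes, pitch rising with
proximity, a hissing collision warning), a **virtual guide** that leads a
user along a waypoint route, and a raw image-to-spectrogram sonification
baseline. Stochastic user agents — with systematic azimuth bias, Gaussian
localization noise, and occasional front–back confusion — run the full
task battery, and the analytics module reproduces the trajectory and
aiming measurements used to quantify performance (deviation index,
2 s moving-average smoothing, phase segmentation, 90th-percentile speeds,
circular aiming statistics, recall regression, Rayleigh uniformity test).

## Package layout

| module | contents |
|---|---|
| `voxnav.scene` | `Pose`, `Scene`, `OccupancyGrid`, `GuidePath`; azimuth/spotlight/scan-order/obstacle queries; JSON (de)serialization |
| `voxnav.sonify` | `AudioEvent`, pitch map, the four assistant modes, collision warning, `voice_encode` spectrogram scan (+ optional WAV rendering) |
| `voxnav.guide` | virtual-guide state machine (`update_guide`), turn-by-turn text, A* wayfinding over the occupancy grid |
| `voxnav.agent` | `AgentProfile`, noisy azimuth perception, task policies (aim, direct navigation, guide following, uninformed search, raw-scan baseline), spatial memory |
| `voxnav.tasks` | the task battery: localization, spatial memory, direct navigation (+ cane-style baseline), guided navigation, three virtual-room benchmark tasks; 5 Hz `TrialLog`s |
| `voxnav.analytics` | smoothing, path length, deviation index, phase onset, speeds, circular aiming stats, recall regression, Rayleigh test, tidy summary tables |
| `voxnav.fixtures` | deterministic scenes: 5-object half circle, 4-chair arena, 9-waypoint 36.4 m building route, 16-object living room |
| `voxnav.log_io` | trial logs as pose CSV + JSON-lines events + JSON metadata |
| `voxnav.cli` | `voxnav` command line |

## Conventions

Right-handed coordinates, x/y horizontal, z up. Yaw is measured from +x,
positive clockwise viewed from above, so **positive relative azimuth is to
the listener's right** and a left-to-right scan is ascending azimuth.
Angles are degrees wrapped to (−180, 180]. Azimuths are horizontal-plane
only. Poses are logged at 5 Hz; simulation integrates at 50 Hz.

## CLI

```bash
# run a task and write trial logs (CSV + JSONL + meta JSON)
voxnav simulate --task direct-nav --profile noiseless --seed 1 --out logs/

# tasks: localization | memory | direct-nav | direct-nav-baseline |
#        guided-nav | benchmark        (benchmark: --sonifier assistant|raw)
# profiles: noiseless | typical | noisy, or a JSON AgentProfile file

# per-trial metric table
voxnav analyze logs/ --out metrics.csv

# metric table + trajectory/aiming plots
voxnav report logs/ --out report/

# regenerate bundled scene fixtures
voxnav fixtures --out fixtures/
```

Identical seeds reproduce byte-identical logs.

## Scene/path config schema (JSON)

```jsonc
{
  "objects":  [{"id": "chair", "label": "chair", "position": [x, y, z], "radius": 0.5}],
  "grid":     {"cell_size": 0.1, "rows": 100, "cols": 100,
               "origin": [x0, y0], "blocked": [[row, col], ...]},
  "start_zone": {"center": [x, y, z], "radius": 0.5},
  "waypoints": [{"xyz": [x, y, z], "turn": "left|right|none",
                 "stairs": false, "segment": "lobby"}],
  "arrival_radius": 1.2
}
```

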