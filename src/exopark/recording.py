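"""The trial-recording container and its CSV/JSON serialization.

A :class:`TrialRecording` is one uniformly-sampled trial of one task:
elbow angle/velocity, per-arm hand positions, applied robot elbow torque,
and a time-sorted event log (spawns, hits, load on/off, movement
boundaries).  Recordings round-trip through one plain rectangular CSV per
trial; the event log and trial metadata live in a ``.events.json`` sidecar
next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["Event", "TrialRecording", "write_trial_csv", "read_trial_csv"]

EVENT_KINDS = {
    "spawn",
    "hit_target",
    "hit_distractor",
    "miss",
    "load_on",
    "load_off",
    "movement_start",
    "movement_end",
}


@dataclass(frozen=True)
class Event:
    time: float
    kind: str
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class TrialRecording:
    """Uniformly sampled bilateral arm state plus an event log for one trial."""

    task: str  # Task enum value
    arm: str  # "left" | "right" | "bilateral"
    t: np.ndarray  # s, uniform grid
    theta_elbow: np.ndarray  # rad
    omega_elbow: np.ndarray  # rad/s
    hand_xy: dict[str, np.ndarray]  # arm -> (n, 2) m
    robot_torque_elbow: np.ndarray  # Nm
    events: list[Event]
    sample_rate: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        t = np.asarray(self.t, dtype=float)
        n = t.size
        if n < 2:
            raise ValueError("recording needs at least 2 samples")
        dt = np.diff(t)
        step = 1.0 / self.sample_rate
        if not np.all(dt > 0):
            raise ValueError("time base must be strictly increasing")
        if not np.allclose(dt, step, rtol=1e-9, atol=1e-9 * step):
            raise ValueError("time base must have constant step 1/sample_rate")
        for name in ("theta_elbow", "omega_elbow", "robot_torque_elbow"):
            if np.asarray(getattr(self, name)).shape != (n,):
                raise ValueError(f"{name} length differs from time base")
        for arm, xy in self.hand_xy.items():
            if np.asarray(xy).shape != (n, 2):
                raise ValueError(f"hand_xy[{arm}] must be (n, 2)")
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be time-sorted")
        if times and (times[0] < t[0] - 1e-9 or times[-1] > t[-1] + 1e-9):
            raise ValueError("event outside the recorded interval")

    def events_of(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def _frame(rec: TrialRecording) -> pd.DataFrame:
    data = {
        "t": rec.t,
        "theta_elbow": rec.theta_elbow,
        "omega_elbow": rec.omega_elbow,
        "robot_torque_elbow": rec.robot_torque_elbow,
    }
    for arm, xy in rec.hand_xy.items():
        data[f"hand_x_{arm}"] = xy[:, 0]
        data[f"hand_y_{arm}"] = xy[:, 1]
    return pd.DataFrame(data)


def write_trial_csv(rec: TrialRecording, path: str | Path) -> None:
    """Write one trial as ``<path>`` (CSV) plus ``<path>.events.json``."""
    path = Path(path)
    _frame(rec).to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "task": rec.task,
        "arm": rec.arm,
        "sample_rate": rec.sample_rate,
        "meta": rec.meta,
        "events": [
            {"time": e.time, "kind": e.kind, "payload": e.payload} for e in rec.events
        ],
    }
    Path(str(path) + ".events.json").write_text(
        json.dumps(sidecar, sort_keys=True), encoding="utf-8"
    )


def read_trial_csv(path: str | Path) -> TrialRecording:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(Path(str(path) + ".events.json").read_text(encoding="utf-8"))
    arms = sorted({c[7:] for c in df.columns if c.startswith("hand_x_")})
    hand_xy = {
        arm: np.column_stack([df[f"hand_x_{arm}"].to_numpy(), df[f"hand_y_{arm}"].to_numpy()])
        for arm in arms
    }
    return TrialRecording(
        task=sidecar["task"],
        arm=sidecar["arm"],
        t=df["t"].to_numpy(),
        theta_elbow=df["theta_elbow"].to_numpy(),
        omega_elbow=df["omega_elbow"].to_numpy(),
        hand_xy=hand_xy,
        robot_torque_elbow=df["robot_torque_elbow"].to_numpy(),
        events=[Event(e["time"], e["kind"], e.get("payload", {})) for e in sidecar["events"]],
        sample_rate=sidecar["sample_rate"],
        meta=sidecar.get("meta", {}),
    )
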