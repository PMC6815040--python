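"""Task-parameter extraction from trial recordings.

One function per task family computes the published parameter set:

* hitting tasks - mean hand speed (m/s), movement area (m^2, summed
  per-hand convex hulls), target and distractor hit counts;
* passive stretch - start/end total torque (Nm s), their difference, hold
  torque, and peak stretch speed (rad/s), averaged over the flexion and
  extension repetitions of one movement-time condition;
* unloading - deceleration time (ms), maximum displacement (m), return
  time (ms), endpoint error (m), averaged over trials, loads and arms.

Torque phase totals are unsigned phase integrals ``|trapz(tau, t)|`` split
at the sample of peak stretch speed (earliest sample on ties).  This makes
the inertial identity ``start = end = I * omega_peak`` and the viscous
identity ``start - end = b * dtheta`` hold exactly for an ideal limb, and
keeps every parameter nonnegative so that a lower end total torque reads
as less braking effort by the robot.

``extract_parameters`` turns a whole simulated cohort into the tidy
exchange table (subject, session, task, parameter, arm, value) used by the
scoring and inference stages.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .recording import TrialRecording

__all__ = [
    "mean_hand_speed",
    "movement_area",
    "count_hits",
    "stretch_torques",
    "total_torque_difference",
    "unloading_features",
    "extract_parameters",
    "parameter_table",
    "PARAMETERS",
]

#: Canonical analysis parameter ids, task-prefixed (oh = object hit,
#: oha = object hit and avoid, ps = passive stretch, ul = unloading).
PARAMETERS = [
    "oh_mean_hand_speed",
    "oh_movement_area",
    "oh_total_hits",
    "oha_mean_hand_speed",
    "oha_movement_area",
    "oha_total_hits",
    "oha_distractor_hits",
    "ps_start_total_torque",
    "ps_end_total_torque",
    "ps_total_torque_difference",
    "ps_hold_torque",
    "ps_peak_speed",
    "ul_deceleration_time",
    "ul_max_displacement",
    "ul_return_time",
    "ul_endpoint_error",
]


def mean_hand_speed(rec: TrialRecording, arm: str) -> float:
    """Time-averaged magnitude of the hand velocity over the full trial."""
    xy = np.asarray(rec.hand_xy[arm], dtype=float)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 samples to differentiate position")
    d = np.diff(xy, axis=0)
    speeds = np.hypot(d[:, 0], d[:, 1]) * rec.sample_rate
    return float(np.mean(speeds))


def _hull_area(xy: np.ndarray) -> float:
    try:
        return float(ConvexHull(xy).volume)  # 2-D: volume is the area
    except QhullError:
        warnings.warn("degenerate hand trajectory: movement area set to 0")
        return 0.0


def movement_area(rec: TrialRecording, arm: str | None = None) -> float:
    """Convex-hull area covered by the hands (m^2).

    With ``arm=None`` the per-hand hull areas are summed, which is the
    task-level 'area covered by both hands' parameter.
    """
    arms = [arm] if arm else sorted(rec.hand_xy)
    return sum(_hull_area(np.asarray(rec.hand_xy[a], dtype=float)) for a in arms)


def count_hits(rec: TrialRecording) -> tuple[int, int]:
    """(target hits, distractor hits), each object counted at most once."""
    seen: set = set()
    totals = {"hit_target": 0, "hit_distractor": 0}
    for e in rec.events:
        if e.kind in totals:
            obj = e.payload.get("object")
            if obj is not None:
                if obj in seen:
                    raise ValueError(f"duplicate hit event for object {obj}")
                seen.add(obj)
            totals[e.kind] += 1
    return totals["hit_target"], totals["hit_distractor"]


def stretch_torques(rec: TrialRecording) -> dict[str, float]:
    """Phase torque totals and peak speed for one imposed movement.

    Returns ``start_total``, ``end_total``, ``difference``, ``hold``
    (all Nm s) and ``peak_speed`` (rad/s).  ``hold`` integrates the wait-
    period torque over the 1 s window from 1.5 s to 0.5 s before movement
    onset, so at least 2 s of pre-movement data are required.
    """
    starts = rec.events_of("movement_start")
    ends = rec.events_of("movement_end")
    if not starts or not ends:
        raise ValueError("movement_start/movement_end events required")
    t = rec.t
    fs = rec.sample_rate
    i0 = int(round((starts[0].time - t[0]) * fs))
    i1 = int(round((ends[0].time - t[0]) * fs))
    if starts[0].time - t[0] < 2.0 - 1e-9:
        raise ValueError("need >= 2 s of pre-movement data for the hold window")
    seg_w = np.abs(rec.omega_elbow[i0 : i1 + 1])
    ipk = i0 + int(np.argmax(seg_w))  # earliest sample on ties
    if ipk in (i0, i1):
        raise ValueError("peak speed at a segment boundary: movement not captured")
    tau = rec.robot_torque_elbow
    start_total = abs(np.trapezoid(tau[i0 : ipk + 1], t[i0 : ipk + 1]))
    end_total = abs(np.trapezoid(tau[ipk : i1 + 1], t[ipk : i1 + 1]))
    h0 = int(round((starts[0].time - 1.5 - t[0]) * fs))
    h1 = int(round((starts[0].time - 0.5 - t[0]) * fs))
    hold = abs(np.trapezoid(tau[h0 : h1 + 1], t[h0 : h1 + 1]))
    return {
        "start_total": float(start_total),
        "end_total": float(end_total),
        "difference": float(start_total - end_total),
        "hold": float(hold),
        "peak_speed": float(seg_w[ipk - i0]),
    }


def total_torque_difference(start_total: float, end_total: float) -> float:
    """Start minus end phase total; positive when the limb assists braking."""
    return start_total - end_total


def unloading_features(rec: TrialRecording) -> dict[str, float]:
    """Postural-response parameters for one load-release trial.

    ``return_time`` is NaN (flagged missing, never infinite) when the hand
    does not re-enter the target at stabilized speed before the trial ends.
    """
    offs = rec.events_of("load_off")
    if not offs:
        raise ValueError("load_off event required")
    t = rec.t
    fs = rec.sample_rate
    i_off = int(round((offs[0].time - t[0]) * fs))
    if t.size - i_off < 3:
        raise ValueError("insufficient post-release data")
    arm = rec.arm if rec.arm in rec.hand_xy else sorted(rec.hand_xy)[0]
    xy = np.asarray(rec.hand_xy[arm], dtype=float)
    center = np.asarray(rec.meta.get("target_center", [0.0, 0.25]), dtype=float)
    dist = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    post = dist[i_off:]
    ipk = i_off + int(np.argmax(post))
    max_disp = float(dist[ipk])
    decel_ms = (t[ipk] - t[i_off]) * 1000.0
    d = np.diff(xy, axis=0)
    speed = np.hypot(d[:, 0], d[:, 1]) * fs
    speed = np.append(speed, speed[-1])
    radius = float(rec.meta.get("target_radius", 0.01))
    stab = float(rec.meta.get("stabilize_speed", 0.02))
    inside = (dist[ipk:] < radius) & (speed[ipk:] < stab)
    hits = np.flatnonzero(inside)
    return_ms = float((hits[0] / fs) * 1000.0) if hits.size else math.nan
    return {
        "deceleration_time": float(decel_ms),
        "max_displacement": max_disp,
        "return_time": return_ms,
        "endpoint_error": float(dist[-1]),
    }


# --------------------------------------------------------------------------
# cohort-level extraction
# --------------------------------------------------------------------------

def _hit_task_rows(rec: TrialRecording, prefix: str) -> list[tuple[str, str, float]]:
    rows = []
    for arm in sorted(rec.hand_xy):
        rows.append((f"{prefix}_mean_hand_speed", arm, mean_hand_speed(rec, arm)))
        rows.append((f"{prefix}_movement_area", arm, movement_area(rec, arm)))
    speeds = [v for p, a, v in rows if p.endswith("mean_hand_speed")]
    areas = [v for p, a, v in rows if p.endswith("movement_area")]
    rows.append((f"{prefix}_mean_hand_speed", "mean", float(np.mean(speeds))))
    rows.append((f"{prefix}_movement_area", "mean", float(np.sum(areas))))
    hits, distractors = count_hits(rec)
    rows.append((f"{prefix}_total_hits", "mean", float(hits)))
    if prefix == "oha":
        rows.append((f"{prefix}_distractor_hits", "mean", float(distractors)))
    return rows


def _stretch_rows(recs: list[TrialRecording], movement_time: float) -> list[tuple[str, str, float]]:
    per_arm: dict[str, list[dict[str, float]]] = {}
    for rec in recs:
        if not math.isclose(rec.meta.get("movement_time", -1.0), movement_time):
            continue
        per_arm.setdefault(rec.arm, []).append(stretch_torques(rec))
    rows = []
    names = {
        "start_total": "ps_start_total_torque",
        "end_total": "ps_end_total_torque",
        "difference": "ps_total_torque_difference",
        "hold": "ps_hold_torque",
        "peak_speed": "ps_peak_speed",
    }
    arm_means: dict[str, dict[str, float]] = {}
    for arm, feats in sorted(per_arm.items()):
        arm_means[arm] = {k: float(np.mean([f[k] for f in feats])) for k in names}
        for k, pid in names.items():
            rows.append((pid, arm, arm_means[arm][k]))
    if arm_means:
        for k, pid in names.items():
            rows.append((pid, "mean", float(np.mean([m[k] for m in arm_means.values()]))))
    return rows


def _unloading_rows(recs: list[TrialRecording]) -> list[tuple[str, str, float]]:
    per_arm: dict[str, list[dict[str, float]]] = {}
    for rec in recs:
        per_arm.setdefault(rec.arm, []).append(unloading_features(rec))
    names = {
        "deceleration_time": "ul_deceleration_time",
        "max_displacement": "ul_max_displacement",
        "return_time": "ul_return_time",
        "endpoint_error": "ul_endpoint_error",
    }
    rows = []
    arm_means: dict[str, dict[str, float]] = {}
    for arm, feats in sorted(per_arm.items()):
        arm_means[arm] = {
            k: float(np.nanmean([f[k] for f in feats])) for k in names
        }
        for k, pid in names.items():
            rows.append((pid, arm, arm_means[arm][k]))
    if arm_means:
        for k, pid in names.items():
            rows.append((pid, "mean", float(np.mean([m[k] for m in arm_means.values()]))))
    return rows


def extract_parameters(cohort, movement_time: float = 0.6) -> pd.DataFrame:
    """Tidy parameter table for a whole cohort.

    Columns: subject, session, task, parameter, arm, value.  The stretch
    parameters are reported for the given movement-time condition (the
    600 ms stretches by default, which discriminate best).
    """
    records = []
    for (sid, session), recs in sorted(cohort.recordings.items()):
        by_task: dict[str, list[TrialRecording]] = {}
        for r in recs:
            by_task.setdefault(r.task, []).append(r)
        rows: list[tuple[str, str, float]] = []
        for r in by_task.get("object_hit", []):
            rows.extend(_hit_task_rows(r, "oh"))
        for r in by_task.get("object_hit_avoid", []):
            rows.extend(_hit_task_rows(r, "oha"))
        rows.extend(_stretch_rows(by_task.get("passive_stretch", []), movement_time))
        rows.extend(_unloading_rows(by_task.get("unloading", [])))
        for pid, arm, value in rows:
            records.append(
                {
                    "subject": sid,
                    "session": session,
                    "task": pid.split("_")[0],
                    "parameter": pid,
                    "arm": arm,
                    "value": value,
                }
            )
    return pd.DataFrame.from_records(records)


def parameter_table(params: pd.DataFrame, arm: str = "mean") -> pd.DataFrame:
    """Pivot the tidy table to wide (subject, session) x parameter."""
    sel = params[params["arm"] == arm]
    wide = sel.pivot_table(
        index=["subject", "session"], columns="parameter", values="value", aggfunc="mean"
    )
    wide.columns.name = None
    return wide
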