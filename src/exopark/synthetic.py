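"""Seeded simulators for the four-task bilateral exoskeleton battery.

Every downstream stage of the pipeline is exercised on recordings produced
here: a bilateral falling-object hitting task (with and without
distractors), a servo-driven passive elbow stretch, and a torque-unloading
postural task.  The simulators are deliberately simple single-joint /
planar models whose latent parameters (:class:`SubjectProfile`) realize the
clinical constructs: reduced ``max_hand_speed`` plays the role of
bradykinesia; elevated tone ``tau0`` (velocity-independent, Coulomb-like),
viscosity ``b`` and reflex stiffness jointly realize rigidity; elevated
postural stiffness ``k`` shortens and quickens the unloading excursion.

Passive-stretch limb model, per arm::

    I * dw/dt = tau_robot - b*w - k_s*(theta - theta_start) - tau0 * S(w)

with ``S(w)`` a sign-with-bias tone term (constant bias at rest so that a
toned limb loads the robot even during the hold period) and ``k_s`` a small
reflex fraction of the postural stiffness.  The robot tracks a commanded
minimum-jerk profile with inertial feedforward plus proportional-derivative
correction; the recorded channel is the controller output torque, exactly
what the physical servo would log.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .config import CohortSpec, ObjectHitConfig, Task, TaskConfig
from .io_clinical import SubjectRecord
from .recording import Event, TrialRecording

__all__ = [
    "SubjectProfile",
    "Cohort",
    "minimum_jerk_profile",
    "simulate_stretch_trial",
    "simulate_object_hit_trial",
    "simulate_unloading_trial",
    "generate_cohort",
    "control_profile",
    "pd_profile",
]

ARMS = ("right", "left")

# Servo-controller gains (Nm/rad, Nm.s/rad) and the nominal viscous
# feedforward (calibrated against a standard healthy limb).  Chosen so that
# a control-range limb tracks the commanded stretch at >= 99% of commanded
# peak speed while a rigid limb shows a clear velocity deficit; see
# docs/methods.md.
SERVO_KP = 25.0
SERVO_KD = 1.5
SERVO_VISCOUS_FF = 0.05  # Nm s/rad, nominal limb viscosity fed forward
# The movement_end event is placed this long after the commanded endpoint so
# the limb has settled to rest and the deceleration phase is fully captured.
STRETCH_SETTLE = 0.25  # s
# Reflex stiffness engaged during imposed stretch, as a fraction of the
# postural stiffness k (the limb resists being carried away from its start).
# Kept small so that stretch resistance is viscosity/tone dominated: a
# position-anchored spring would make the robot push (rather than brake)
# through late deceleration in severely rigid limbs, inverting the
# end-total-torque group difference.
STRETCH_STIFFNESS_FRACTION = 0.01
# |omega| below which the tone term sits at its constant resting bias.
TONE_OMEGA_EPS = 0.05  # rad/s
# Effective hand lever arms used to map single-joint angle to hand position.
HAND_RADIUS = {"elbow": 0.30, "shoulder": 0.35}  # m
# Subject corrective posture controller (unloading task).  Deliberately
# soft so that the passive limb stiffness k dominates both the excursion
# amplitude and its timing.
POSTURE_KP = 5.0
POSTURE_KD = 0.8
POSTURE_RELAX_TAU = 0.10  # s, decay of the obsolete resisting torque
# Reference healthy hand-speed cap; pursuit amplitude scales with the ratio
# of a subject's cap to this value (speed-amplitude coupling: bradykinetic
# subjects also make smaller excursions from their home position).
BASE_HAND_SPEED = 0.45  # m/s


@dataclass(frozen=True)
class SubjectProfile:
    """Latent generative parameters for one (simulated) participant.

    Per-arm fields are ``{"right": value, "left": value}`` maps; the
    asymmetry of a parkinsonian profile lives entirely in those maps.
    """

    max_hand_speed: dict[str, float]  # m/s per arm
    motor_lag: float  # s, first-order pursuit lag
    inertia: float  # kg m^2, forearm about the elbow
    viscosity: dict[str, float]  # Nm s/rad per arm
    stiffness: dict[str, float]  # Nm/rad per arm (postural)
    tone: dict[str, float]  # Nm per arm (velocity-independent)
    reaction_delay: float  # s
    proprioceptive_noise: float  # m (sd of perceived target offset)
    p_err: float  # distractor engagement probability
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("max_hand_speed", "viscosity", "stiffness", "tone"):
            for arm, v in getattr(self, name).items():
                if v < 0:
                    raise ValueError(f"{name}[{arm}] must be >= 0")
        if not 0 <= self.p_err <= 1:
            raise ValueError("p_err must be in [0, 1]")
        for name in ("motor_lag", "inertia", "proprioceptive_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def control_profile(**overrides) -> SubjectProfile:
    """A deterministic mid-range healthy profile (useful in tests)."""
    base = dict(
        max_hand_speed={"right": BASE_HAND_SPEED, "left": BASE_HAND_SPEED},
        motor_lag=0.10,
        inertia=0.06,
        viscosity={"right": 0.05, "left": 0.05},
        stiffness={"right": 4.0, "left": 4.0},
        tone={"right": 0.02, "left": 0.02},
        reaction_delay=0.12,
        proprioceptive_noise=0.006,
        p_err=0.20,
    )
    base.update(overrides)
    return SubjectProfile(**base)


def pd_profile(severity: float = 1.0, spec: CohortSpec | None = None,
               session: str = "off", **overrides) -> SubjectProfile:
    """A deterministic parkinsonian profile with planted group effects."""
    spec = spec or CohortSpec()
    m = spec.off if session == "off" else spec.on
    eff = lambda mult: 1.0 + (mult - 1.0) * severity
    base = control_profile()
    prof = replace(
        base,
        max_hand_speed={a: v * eff(m.speed) for a, v in base.max_hand_speed.items()},
        viscosity={a: v * eff(m.viscosity) for a, v in base.viscosity.items()},
        stiffness={a: v * eff(m.stiffness) for a, v in base.stiffness.items()},
        tone={a: v * eff(m.tone) for a, v in base.tone.items()},
        p_err=min(1.0, base.p_err * eff(m.p_err)),
        meta={"severity": severity, "session": session},
    )
    if overrides:
        prof = replace(prof, **overrides)
    return prof


# --------------------------------------------------------------------------
# minimum-jerk kinematics
# --------------------------------------------------------------------------

def minimum_jerk_profile(
    theta_start: float, theta_end: float, T: float, sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk angle/velocity profile from ``theta_start`` to ``theta_end``.

    The bell-shaped velocity peaks at ``1.875 * |dtheta| / T`` at mid-
    movement, with zero velocity and acceleration at both ends.
    """
    if T <= 0:
        raise ValueError("movement time T must be positive")
    n = int(round(T * sample_rate)) + 1
    s = np.linspace(0.0, 1.0, n)
    d = theta_end - theta_start
    theta = theta_start + d * (10 * s**3 - 15 * s**4 + 6 * s**5)
    omega = d / T * (30 * s**2 - 60 * s**3 + 30 * s**4)
    return theta, omega


def _minimum_jerk_accel(theta_start: float, theta_end: float, T: float, n: int) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n)
    d = theta_end - theta_start
    return d / T**2 * (60 * s - 180 * s**2 + 120 * s**3)


# --------------------------------------------------------------------------
# passive stretch
# --------------------------------------------------------------------------

def simulate_stretch_trial(
    profile: SubjectProfile,
    config: TaskConfig,
    direction: Literal["flexion", "extension"],
    T: float,
    seed: int,
    arm: str = "right",
    corrective_gains: tuple[float, float] = (SERVO_KP, SERVO_KD),
    stiffness_fraction: float = STRETCH_STIFFNESS_FRACTION,
    viscous_feedforward: float = SERVO_VISCOUS_FF,
) -> TrialRecording:
    """Simulate one imposed elbow movement (flexion or extension).

    The trial comprises a randomized hold period (>= 2 s of pre-movement
    data), the commanded minimum-jerk movement bracketed by
    ``movement_start``/``movement_end`` events, and a short tail.
    """
    ps = config.passive_stretch
    if not any(math.isclose(T, mt) for mt in ps.movement_times):
        raise ValueError(f"T={T} not one of the configured movement times {ps.movement_times}")
    rng = np.random.default_rng(seed)
    fs = config.sample_rate
    dt = 1.0 / fs
    lo, hi = (math.radians(a) for a in ps.elbow_range_deg)
    if direction == "flexion":
        th0, th1 = hi, lo
    elif direction == "extension":
        th0, th1 = lo, hi
    else:
        raise ValueError("direction must be 'flexion' or 'extension'")

    wait = float(rng.uniform(ps.wait_min, ps.wait_max))
    n_wait = int(round(wait * fs))
    th_cmd_mov, om_cmd_mov = minimum_jerk_profile(th0, th1, T, fs)
    al_cmd_mov = _minimum_jerk_accel(th0, th1, T, th_cmd_mov.size)
    n_tail = int(round(ps.tail * fs))

    theta_cmd = np.concatenate(
        [np.full(n_wait, th0), th_cmd_mov, np.full(n_tail, th1)]
    )
    omega_cmd = np.concatenate([np.zeros(n_wait), om_cmd_mov, np.zeros(n_tail)])
    alpha_cmd = np.concatenate([np.zeros(n_wait), al_cmd_mov, np.zeros(n_tail)])
    n = theta_cmd.size
    t = np.arange(n) * dt

    kp, kd = corrective_gains
    inertia = profile.inertia
    b = profile.viscosity[arm]
    k_s = stiffness_fraction * profile.stiffness[arm]
    tau0 = profile.tone[arm]

    theta = np.empty(n)
    omega = np.empty(n)
    torque = np.empty(n)
    th, om = th0, 0.0
    for i in range(n):
        tau_r = (
            inertia * alpha_cmd[i]
            + viscous_feedforward * omega_cmd[i]
            + kp * (theta_cmd[i] - th)
            + kd * (omega_cmd[i] - om)
        )
        if om > TONE_OMEGA_EPS:
            tone = tau0
        elif om < -TONE_OMEGA_EPS:
            tone = -tau0
        else:
            tone = -tau0  # resting flexor bias; the robot must counter it
        acc = (tau_r - b * om - k_s * (th - th0) - tone) / inertia
        om += acc * dt
        th += om * dt
        theta[i] = th
        omega[i] = om
        torque[i] = tau_r
        if not math.isfinite(th) or abs(th - th0) > 10.0:
            raise RuntimeError("unstable servo controller: trajectory diverged")

    t_start = n_wait * dt
    i_end = min(n_wait + th_cmd_mov.size - 1 + int(round(STRETCH_SETTLE * fs)), n - 1)
    t_end = i_end * dt
    events = [
        Event(t_start, "movement_start", {"direction": direction, "T": T, "arm": arm}),
        Event(t_end, "movement_end", {"direction": direction, "T": T, "arm": arm}),
    ]
    hand = np.column_stack(
        [HAND_RADIUS["elbow"] * np.cos(theta), HAND_RADIUS["elbow"] * np.sin(theta)]
    )
    return TrialRecording(
        task=Task.PASSIVE_STRETCH.value,
        arm=arm,
        t=t,
        theta_elbow=theta,
        omega_elbow=omega,
        hand_xy={arm: hand},
        robot_torque_elbow=torque,
        events=events,
        sample_rate=fs,
        meta={"direction": direction, "movement_time": T, "wait": wait,
              "commanded_peak_speed": float(np.max(np.abs(om_cmd_mov)))},
    )


# --------------------------------------------------------------------------
# object hit (with and without distractors)
# --------------------------------------------------------------------------

def _spawn_schedule(oh: ObjectHitConfig, rng: np.random.Generator):
    n = oh.n_targets + oh.n_distractors
    spawn_t = (np.arange(n) + 1.0) * oh.duration / (n + 1)
    if n > 1:
        speeds = oh.speed_start + (oh.speed_end - oh.speed_start) * np.arange(n) / (n - 1)
    else:
        speeds = np.array([oh.speed_start])
    reps = int(math.ceil(n / oh.spawn_bins))
    bins = rng.permutation(np.tile(np.arange(oh.spawn_bins), reps)[:n])
    cls = np.zeros(n, dtype=int)  # 0 target, 1 distractor
    if oh.n_distractors:
        cls[rng.choice(n, size=oh.n_distractors, replace=False)] = 1
    return spawn_t, speeds, bins, cls


def bin_center_x(oh: ObjectHitConfig, bin_index: int) -> float:
    """Workspace x of a spawn bin center (bins tile the width uniformly)."""
    w = oh.workspace_width
    return -w / 2.0 + (bin_index + 0.5) * w / oh.spawn_bins


def simulate_object_hit_trial(
    profile: SubjectProfile,
    config: TaskConfig,
    avoid_mode: bool,
    seed: int,
    home: dict[str, tuple[float, float]] | None = None,
) -> TrialRecording:
    """Simulate one bilateral hitting trial.

    Objects fall from ``spawn_bins`` locations with a monotone speed ramp.
    Each hand pursues the nearest active object on its own half of the
    workspace with a speed-capped first-order lag; distractors are engaged
    with probability ``p_err`` (decided once per object) and are otherwise
    transparent to the paddles, so ``p_err = 0`` guarantees zero distractor
    hits.  A hit is logged once per object when its center passes within
    ``(paddle_width + target_diameter) / 2`` of a hand.
    """
    oh = config.object_hit_avoid if avoid_mode else config.object_hit
    if avoid_mode and oh.n_distractors == 0:
        raise ValueError("avoid mode requires n_distractors > 0")
    if not avoid_mode and oh.n_distractors != 0:
        raise ValueError("plain object-hit config must have no distractors")
    rng = np.random.default_rng(seed)
    fs = config.sample_rate
    dt = 1.0 / fs
    spawn_t, speeds, bins, cls = _spawn_schedule(oh, rng)
    n_obj = spawn_t.size
    engaged = (cls == 0) | (rng.random(n_obj) < profile.p_err)
    obj_x = np.array([bin_center_x(oh, b) for b in bins])
    height = oh.workspace_height
    hit_r = oh.hit_radius
    y_lo, y_hi = 0.10, 0.70 * height  # paddle strike band

    home = home or {"right": (0.10, 0.12), "left": (-0.10, 0.12)}
    pos = {a: [float(home[a][0]), float(home[a][1])] for a in ARMS}
    vmax = {a: profile.max_hand_speed[a] for a in ARMS}
    amp = {a: min(vmax[a] / BASE_HAND_SPEED, 1.0) for a in ARMS}
    lag = max(profile.motor_lag, dt)

    n = int(round(oh.duration * fs)) + 1
    t = np.arange(n) * dt
    hands = {a: np.empty((n, 2)) for a in ARMS}
    events: list[Event] = []
    active: list[int] = []  # spawned, not resolved
    next_spawn = 0
    total_released = 0

    for i in range(n):
        now = t[i]
        while next_spawn < n_obj and spawn_t[next_spawn] <= now:
            j = next_spawn
            events.append(
                Event(now, "spawn", {
                    "object": int(j), "bin": int(bins[j]),
                    "speed": float(speeds[j]),
                    "cls": "distractor" if cls[j] else "target",
                })
            )
            active.append(j)
            next_spawn += 1
            total_released += 1
        # resolve objects that reached the floor
        still = []
        for j in active:
            y = height - speeds[j] * (now - spawn_t[j])
            if y <= 0.0:
                events.append(Event(now, "miss", {
                    "object": int(j),
                    "cls": "distractor" if cls[j] else "target"}))
            else:
                still.append(j)
        active = still

        for a in ARMS:
            px, py = pos[a]
            side = 1.0 if a == "right" else -1.0
            best, best_d2 = None, math.inf
            for j in active:
                if not engaged[j]:
                    continue
                ox = obj_x[j]
                if ox * side < 0:
                    continue
                oy = height - speeds[j] * (now - spawn_t[j])
                d2 = (ox - px) ** 2 + (oy - py) ** 2
                # only chase balls that are plausibly interceptable before
                # they reach the floor (slow subjects give up on far ones)
                time_to_floor = oy / speeds[j]
                if math.sqrt(d2) > vmax[a] * time_to_floor + hit_r:
                    continue
                if d2 < best_d2:
                    best, best_d2 = j, d2
            if best is None:
                tx, ty = home[a]
            else:
                oy = height - speeds[best] * (now - spawn_t[best])
                tx = home[a][0] + amp[a] * (obj_x[best] - home[a][0])
                ty = min(max(oy, y_lo), y_hi)
            vx = (tx - px) / lag
            vy = (ty - py) / lag
            sp = math.hypot(vx, vy)
            cap = vmax[a]
            if sp > cap and sp > 0:
                vx *= cap / sp
                vy *= cap / sp
            px += vx * dt
            py += vy * dt
            pos[a] = [px, py]
            hands[a][i, 0] = px
            hands[a][i, 1] = py

        # contact check (engaged objects only; transparent distractors skip)
        still = []
        for j in active:
            if not engaged[j]:
                still.append(j)
                continue
            oy = height - speeds[j] * (now - spawn_t[j])
            hit_by = None
            for a in ARMS:
                if (obj_x[j] - pos[a][0]) ** 2 + (oy - pos[a][1]) ** 2 <= hit_r**2:
                    hit_by = a
                    break
            if hit_by is not None:
                kind = "hit_distractor" if cls[j] else "hit_target"
                events.append(Event(now, kind, {
                    "object": int(j), "hand": hit_by, "bin": int(bins[j]),
                    "speed": float(speeds[j])}))
            else:
                still.append(j)
        active = still

    zeros = np.zeros(n)
    return TrialRecording(
        task=(Task.OBJECT_HIT_AVOID if avoid_mode else Task.OBJECT_HIT).value,
        arm="bilateral",
        t=t,
        theta_elbow=zeros,
        omega_elbow=zeros,
        hand_xy=hands,
        robot_torque_elbow=zeros,
        events=events,
        sample_rate=fs,
        meta={"avoid_mode": avoid_mode, "n_released": int(total_released)},
    )


# --------------------------------------------------------------------------
# torque unloading
# --------------------------------------------------------------------------

def simulate_unloading_trial(
    profile: SubjectProfile,
    config: TaskConfig,
    load: float,
    joint: Literal["elbow", "shoulder"],
    feedback: bool,
    seed: int,
    arm: str = "right",
    corrective: bool = True,
) -> TrialRecording:
    """Simulate one load-hold / sudden-release postural trial.

    The subject holds the hand on the target against a constant joint
    torque; at a random delay the load vanishes and the now-unopposed
    muscle torque displaces the limb until (``reaction_delay`` later) a
    corrective controller pulls the hand back.  Without visual feedback the
    perceived target is offset by a per-trial proprioceptive error.  With
    ``corrective=False`` the limb responds passively (spring-damper step
    response), which is the closed-form regime used by the tests.
    """
    ul = config.unloading
    mag = ul.elbow_load if joint == "elbow" else ul.shoulder_load
    if not math.isclose(abs(load), mag):
        raise ValueError(f"|load| must equal the configured {joint} magnitude {mag}")
    rng = np.random.default_rng(seed)
    fs = config.sample_rate
    dt = 1.0 / fs
    delay = float(rng.uniform(ul.delay_min, ul.delay_max))
    n_hold = int(round(delay * fs))
    n_tail = int(round(ul.tail * fs))
    n = n_hold + n_tail + 1
    t = np.arange(n) * dt
    t_rel = n_hold * dt

    inertia = profile.inertia
    b = profile.viscosity[arm]
    k = profile.stiffness[arm]
    r = HAND_RADIUS[joint]
    eps = float(rng.normal(0.0, profile.proprioceptive_noise)) / r if not feedback else 0.0
    react = profile.reaction_delay if corrective else math.inf

    theta = np.zeros(n)
    omega = np.zeros(n)
    applied = np.zeros(n)
    applied[: n_hold + 1] = load
    sgn = 1.0 if load >= 0 else -1.0
    th, om = 0.0, 0.0
    for i in range(n_hold + 1, n):
        since = t[i] - t_rel
        if since < react:
            tau_s = -load  # still resisting the vanished load
        else:
            relax = -load * math.exp(-(since - react) / POSTURE_RELAX_TAU)
            tau_s = relax - POSTURE_KP * (th - eps) - POSTURE_KD * om
        acc = (tau_s - b * om - k * th) / inertia
        om += acc * dt
        th += om * dt
        theta[i] = th
        omega[i] = om

    center = np.array([0.0, 0.25])
    hand = np.column_stack([center[0] + sgn * r * theta * -1.0, np.full(n, center[1])])
    # displacement direction: opposite the released load
    events = [
        Event(0.0, "load_on", {"joint": joint, "load": load, "feedback": feedback}),
        Event(t_rel, "load_off", {"joint": joint, "load": load, "feedback": feedback}),
    ]
    return TrialRecording(
        task=Task.UNLOADING.value,
        arm=arm,
        t=t,
        theta_elbow=theta,
        omega_elbow=omega,
        hand_xy={arm: hand},
        robot_torque_elbow=applied,
        events=events,
        sample_rate=fs,
        meta={"joint": joint, "load": load, "feedback": feedback,
              "target_center": [float(center[0]), float(center[1])],
              "target_radius": ul.target_radius,
              "stabilize_speed": ul.stabilize_speed,
              "lever_arm": r},
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """A simulated cohort: subject records plus all task recordings."""

    spec: CohortSpec
    tasks: TaskConfig
    seed: int
    subjects: list[SubjectRecord]
    profiles: dict[tuple[str, str], SubjectProfile]  # (subject, session) -> profile
    recordings: dict[tuple[str, str], list[TrialRecording]]

    def sessions(self) -> list[tuple[str, str]]:
        return sorted(self.recordings.keys())

    def manifest(self) -> dict:
        trials = {
            f"{sid}/{session}": [
                {"task": r.task, "arm": r.arm, "n_samples": int(r.t.size),
                 "n_events": len(r.events)}
                for r in recs
            ]
            for (sid, session), recs in sorted(self.recordings.items())
        }
        return {
            "seed": self.seed,
            "config_hash": self.tasks.config_hash(),
            "spec": json.loads(self.spec.model_dump_json()),
            "subjects": [
                {"subject_id": s.subject_id, "group": s.group, "age": s.age,
                 "sex": s.sex, "handedness": s.handedness,
                 "updrs3_off": s.updrs3_off, "updrs3_on": s.updrs3_on}
                for s in self.subjects
            ],
            "trials": trials,
        }

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), sort_keys=True)

    def manifest_hash(self) -> str:
        return hashlib.sha256(self.manifest_json().encode()).hexdigest()


def _truncated_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise ValueError("unsatisfiable distribution spec (truncation rejected 1000 draws)")


def _sample_base_profile(rng, age: float, spec: CohortSpec) -> SubjectProfile:
    speed = BASE_HAND_SPEED + spec.age_speed_slope * (age - 60.0) + rng.normal(0.0, 0.03)
    speed = max(speed, 0.15)
    arm_jit = {a: float(rng.normal(1.0, 0.02)) for a in ARMS}
    return SubjectProfile(
        max_hand_speed={a: speed * arm_jit[a] for a in ARMS},
        motor_lag=0.10,
        inertia=float(max(rng.normal(0.06, 0.006), 0.03)),
        viscosity={a: float(max(rng.normal(0.05, 0.008), 0.01)) for a in ARMS},
        stiffness={a: float(max(rng.normal(4.0, 0.5), 1.0)) for a in ARMS},
        tone={a: float(abs(rng.normal(0.02, 0.005))) for a in ARMS},
        reaction_delay=float(max(rng.normal(0.12, 0.01), 0.05)),
        proprioceptive_noise=float(abs(rng.normal(0.006, 0.0015))),
        p_err=float(min(max(rng.normal(0.20, 0.04), 0.0), 1.0)),
    )


def _apply_effects(base: SubjectProfile, mult, severity: float,
                   affected: str, asym: float) -> SubjectProfile:
    def per_arm(values: dict[str, float], m: float) -> dict[str, float]:
        out = {}
        for a, v in values.items():
            s_arm = severity * (asym if a == affected else 1.0)
            out[a] = max(v * (1.0 + (m - 1.0) * s_arm), 0.0)
        return out

    return replace(
        base,
        max_hand_speed=per_arm(base.max_hand_speed, mult.speed),
        viscosity=per_arm(base.viscosity, mult.viscosity),
        stiffness=per_arm(base.stiffness, mult.stiffness),
        tone=per_arm(base.tone, mult.tone),
        p_err=float(min(base.p_err * (1.0 + (mult.p_err - 1.0) * severity), 1.0)),
    )


def _session_trials(profile: SubjectProfile, tasks: TaskConfig,
                    rng: np.random.Generator) -> list[TrialRecording]:
    recs = [
        simulate_object_hit_trial(profile, tasks, False, int(rng.integers(2**31))),
        simulate_object_hit_trial(profile, tasks, True, int(rng.integers(2**31))),
    ]
    ps = tasks.passive_stretch
    for arm in ARMS:
        for T in ps.movement_times:
            for _ in range(ps.reps_per_direction):
                for direction in ("flexion", "extension"):
                    recs.append(
                        simulate_stretch_trial(
                            profile, tasks, direction, T,
                            int(rng.integers(2**31)), arm=arm,
                        )
                    )
    ul = tasks.unloading
    for arm in ARMS:
        for joint in ul.joints:
            mag = ul.elbow_load if joint == "elbow" else ul.shoulder_load
            for sign in (1.0, -1.0):
                for trial in range(ul.trials_per_condition):
                    recs.append(
                        simulate_unloading_trial(
                            profile, tasks, sign * mag, joint,
                            feedback=trial < ul.feedback_trials,
                            seed=int(rng.integers(2**31)), arm=arm,
                        )
                    )
    return recs


def generate_cohort(
    spec: CohortSpec, seed: int, tasks: TaskConfig | None = None
) -> Cohort:
    """Generate a full control + PD cohort with planted group effects.

    Deterministic given ``(spec, tasks, seed)``.  Controls get one
    ``baseline`` session; each PD subject gets ``off`` and ``on`` sessions
    whose profiles share the same base physiology and differ only through
    the session effect multipliers.  Synthetic UPDRS-III totals are tied to
    the latent severity so that clinical and robotic measures co-vary.
    """
    tasks = tasks or TaskConfig()
    rng = np.random.default_rng(seed)
    lo, hi = spec.age_range
    subjects: list[SubjectRecord] = []
    profiles: dict[tuple[str, str], SubjectProfile] = {}
    recordings: dict[tuple[str, str], list[TrialRecording]] = {}

    for i in range(spec.n_controls):
        sid = f"C{i + 1:03d}"
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, lo, hi)
        sex = "F" if rng.random() < spec.p_female else "M"
        hand = "left" if rng.random() < spec.p_left_handed else "right"
        prof = _sample_base_profile(rng, age, spec)
        subjects.append(SubjectRecord(sid, "control", age, sex, hand))
        profiles[(sid, "baseline")] = prof
        recordings[(sid, "baseline")] = _session_trials(prof, tasks, rng)

    for i in range(spec.n_pd):
        sid = f"PD{i + 1:03d}"
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, lo, hi)
        sex = "F" if rng.random() < spec.p_female else "M"
        hand = "left" if rng.random() < spec.p_left_handed else "right"
        severity = float(np.clip(rng.normal(1.0, spec.severity_sd), 0.4, 1.8))
        affected = "right" if rng.random() < 0.5 else "left"
        base = _sample_base_profile(rng, age, spec)
        off_prof = _apply_effects(base, spec.off, severity, affected, spec.asymmetry)
        on_prof = _apply_effects(base, spec.on, severity, affected, spec.asymmetry)
        updrs_off = int(np.clip(round(6 + 24 * severity + rng.normal(0, 3)), 3, 80))
        delta = int(round(11 * severity + rng.normal(0, 5)))
        updrs_on = int(max(updrs_off - delta, 1))
        subjects.append(
            SubjectRecord(
                sid, "PD", age, sex, hand,
                disease_duration=float(np.clip(rng.normal(5.5, 3.4), 0.5, 20.0)),
                levodopa_dose=float(np.clip(round(rng.normal(650, 200) / 25) * 25, 300, 1375)),
                updrs3_off=updrs_off,
                updrs3_on=updrs_on,
                moca=int(np.clip(round(rng.normal(25.5, 2.5)), 20, 30)),
            )
        )
        for session, prof in (("off", off_prof), ("on", on_prof)):
            prof = replace(prof, meta={"severity": severity, "affected": affected})
            profiles[(sid, session)] = prof
            recordings[(sid, session)] = _session_trials(prof, tasks, rng)

    return Cohort(spec=spec, tasks=tasks, seed=seed, subjects=subjects,
                  profiles=profiles, recordings=recordings)
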