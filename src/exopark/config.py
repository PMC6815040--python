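"""Validated configuration models for tasks, cohorts, and pipeline runs.

All knobs that the simulators and analyses expose live here as pydantic
models so that a run is fully described by one JSON document.  Defaults
reproduce the study conditions of the four-task bilateral exoskeleton
battery: a 300-ball object-hit block, a 200-target/100-distractor
hit-and-avoid block, 5 flexion + 5 extension passive elbow stretches at two
movement times over the 65-145 degree range, and a 16-trial-per-condition
torque-unloading block at +/-0.5 Nm (elbow) and +/-1 Nm (shoulder).
"""

from __future__ import annotations

import hashlib
import json
import math
from enum import Enum
from typing import Literal

from pydantic import BaseModel, Field, model_validator


class Task(str, Enum):
    OBJECT_HIT = "object_hit"
    OBJECT_HIT_AVOID = "object_hit_avoid"
    PASSIVE_STRETCH = "passive_stretch"
    UNLOADING = "unloading"


class ObjectHitConfig(BaseModel):
    """Falling-object hitting task (with or without distractors)."""

    n_targets: int = Field(300, gt=0)
    n_distractors: int = Field(0, ge=0)  # 100 in avoid mode, 200 targets
    spawn_bins: int = Field(10, gt=0)
    speed_start: float = Field(0.10, gt=0)  # m/s at first spawn
    speed_end: float = Field(0.50, gt=0)  # m/s at last spawn
    target_diameter: float = Field(0.02, gt=0)  # m
    paddle_width: float = Field(0.05, gt=0)  # m
    duration: float = Field(150.0, gt=0)  # s
    workspace_width: float = Field(0.8, gt=0)  # m (x extent)
    workspace_height: float = Field(0.5, gt=0)  # m (y extent)

    @model_validator(mode="after")
    def _ramp_monotone(self):
        if self.speed_end < self.speed_start:
            raise ValueError("object speed ramp must be non-decreasing")
        return self

    @property
    def hit_radius(self) -> float:
        # center-to-center contact distance; no contact mechanics modeled
        return (self.paddle_width + self.target_diameter) / 2.0


class PassiveStretchConfig(BaseModel):
    """Servo-driven elbow flexion/extension over a fixed angular range."""

    elbow_range_deg: tuple[float, float] = (65.0, 145.0)
    shoulder_fixed_deg: float = 60.0
    movement_times: tuple[float, ...] = (0.6, 1.5)  # s
    reps_per_direction: int = Field(5, gt=0)
    wait_min: float = Field(3.0, gt=0)  # s, pre-movement hold
    wait_max: float = Field(6.0, gt=0)
    tail: float = Field(0.5, ge=0)  # s recorded after movement_end

    @model_validator(mode="after")
    def _range_ok(self):
        lo, hi = self.elbow_range_deg
        if not lo < hi:
            raise ValueError("elbow_range start must be < end")
        if self.wait_max < self.wait_min:
            raise ValueError("wait_max < wait_min")
        if any(t <= 0 for t in self.movement_times):
            raise ValueError("movement times must be positive")
        return self

    @property
    def amplitude_rad(self) -> float:
        lo, hi = self.elbow_range_deg
        return math.radians(hi - lo)


class UnloadingConfig(BaseModel):
    """Constant-torque postural hold with sudden load release."""

    elbow_load: float = Field(0.5, gt=0)  # Nm, applied as +/-
    shoulder_load: float = Field(1.0, gt=0)  # Nm, applied as +/-
    trials_per_condition: int = Field(16, gt=0)
    feedback_trials: int = Field(8, ge=0)  # first trials with cursor visible
    joints: tuple[Literal["elbow", "shoulder"], ...] = ("elbow", "shoulder")
    delay_min: float = Field(1.0, gt=0)  # s, random pre-release hold window
    delay_max: float = Field(3.0, gt=0)
    tail: float = Field(2.5, gt=0)  # s recorded after load_off
    target_radius: float = Field(0.015, gt=0)  # m, return criterion
    stabilize_speed: float = Field(0.02, gt=0)  # m/s, return criterion

    @model_validator(mode="after")
    def _window_ok(self):
        if self.delay_max < self.delay_min:
            raise ValueError("delay_max < delay_min")
        return self


class TaskConfig(BaseModel):
    """Full task battery configuration plus the shared sampling rate."""

    sample_rate: float = Field(1000.0, gt=0)  # Hz
    object_hit: ObjectHitConfig = ObjectHitConfig()
    object_hit_avoid: ObjectHitConfig = ObjectHitConfig(n_targets=200, n_distractors=100)
    passive_stretch: PassiveStretchConfig = PassiveStretchConfig()
    unloading: UnloadingConfig = UnloadingConfig()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class EffectMultipliers(BaseModel):
    """Group-level planted effects applied to a parkinsonian profile.

    Values are multipliers on the control-profile latent parameters; 1.0
    everywhere yields a null cohort.  Defaults encode the reported OFF-state
    group differences (hand speed 41% slower; baseline tone 3.6x; elevated
    viscosity driving the lower end-torque / higher torque-difference
    pattern; elevated stiffness driving the 29% shorter unloading
    displacement and faster deceleration).
    """

    speed: float = Field(1.0, ge=0)  # multiplies max_hand_speed
    tone: float = Field(1.0, ge=0)  # multiplies tone torque tau0
    viscosity: float = Field(1.0, ge=0)  # multiplies b
    stiffness: float = Field(1.0, ge=0)  # multiplies k
    p_err: float = Field(1.0, ge=0)  # multiplies distractor error rate


class CohortSpec(BaseModel):
    """Specification of a simulated control + PD cohort.

    ``off``/``on`` multipliers describe the parkinsonian state relative to
    controls in the two medication sessions; the ON defaults partially
    normalize speed and stiffness and reduce tone while leaving viscosity
    at its OFF level, and raise the distractor error rate (the reported
    post-DRT impulsivity direction).
    """

    n_controls: int = Field(40, gt=0)
    n_pd: int = Field(26, gt=0)
    age_mean: float = 64.9
    age_sd: float = Field(8.7, ge=0)
    age_range: tuple[float, float] = (40.0, 85.0)
    p_female: float = Field(5 / 26, ge=0, le=1)
    p_left_handed: float = Field(4 / 26, ge=0, le=1)
    off: EffectMultipliers = EffectMultipliers(
        speed=0.59, tone=3.6, viscosity=3.0, stiffness=1.45, p_err=1.0
    )
    on: EffectMultipliers = EffectMultipliers(
        speed=0.76, tone=2.2, viscosity=2.9, stiffness=1.25, p_err=1.6
    )
    asymmetry: float = Field(1.3, ge=1.0)  # deficit multiplier, most affected arm
    severity_sd: float = Field(0.20, ge=0)  # between-subject spread of disease severity
    age_speed_slope: float = -0.004  # m/s per year, applied to max_hand_speed

    @model_validator(mode="after")
    def _age_ok(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range start must be < end")
        if self.age_sd == 0 and lo < self.age_mean < hi:
            pass  # degenerate but satisfiable
        if self.age_sd == 0 and not (lo <= self.age_mean <= hi):
            raise ValueError("zero-variance age outside the allowed range is unsatisfiable")
        return self


class RunConfig(BaseModel):
    """End-to-end pipeline run: cohort, tasks, thresholds, seeds, output."""

    cohort: CohortSpec = CohortSpec()
    tasks: TaskConfig = TaskConfig()
    mcd_threshold: int = Field(6, ge=0)
    selection_alpha: float = Field(0.05, gt=0, lt=1)  # DRT-sensitivity selection
    gate_alpha: float = Field(0.05, gt=0, lt=1)  # Shapiro-Wilk normality gate
    group_alpha: float = Field(0.01, gt=0, lt=1)  # control-vs-PD group means
    frozen_parameters: list[str] | None = None  # bypass data-driven selection
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def reduced_task_config(sample_rate: float = 200.0) -> TaskConfig:
    """A down-scaled battery for fast Monte-Carlo studies.

    Shorter hitting blocks (90 balls / 45 s), three stretch reps per
    direction at the 600 ms movement time only, and a 3-trial elbow-only
    unloading block.  Planted group effects and all geometry are unchanged;
    only problem sizes shrink.
    """
    return TaskConfig(
        sample_rate=sample_rate,
        object_hit=ObjectHitConfig(n_targets=90, duration=45.0),
        object_hit_avoid=ObjectHitConfig(n_targets=60, n_distractors=30, duration=45.0),
        passive_stretch=PassiveStretchConfig(
            movement_times=(0.6,), reps_per_direction=3, wait_min=2.5, wait_max=3.5
        ),
        unloading=UnloadingConfig(
            trials_per_condition=3, feedback_trials=2, joints=("elbow",), tail=2.0
        ),
    )
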