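import pytest

from exopark.config import (
    CohortSpec,
    ObjectHitConfig,
    PassiveStretchConfig,
    TaskConfig,
    UnloadingConfig,
    reduced_task_config,
)
from exopark.synthetic import generate_cohort


@pytest.fixture(scope="session")
def tasks_fast() -> TaskConfig:
    """Down-scaled task battery at 100 Hz for quick simulation tests."""
    return reduced_task_config(100.0)


@pytest.fixture(scope="session")
def tasks_tiny() -> TaskConfig:
    """Minimal battery: a handful of objects/trials, for plumbing tests."""
    return TaskConfig(
        sample_rate=100.0,
        object_hit=ObjectHitConfig(n_targets=10, duration=10.0),
        object_hit_avoid=ObjectHitConfig(n_targets=8, n_distractors=4, duration=10.0),
        passive_stretch=PassiveStretchConfig(
            movement_times=(0.6,), reps_per_direction=1, wait_min=2.5, wait_max=3.0
        ),
        unloading=UnloadingConfig(
            trials_per_condition=1, feedback_trials=1, joints=("elbow",), tail=1.5
        ),
    )


@pytest.fixture(scope="session")
def small_cohort(tasks_fast):
    """One seeded 8-control / 8-PD cohort shared across feature/scoring tests."""
    return generate_cohort(CohortSpec(n_controls=8, n_pd=8), seed=11, tasks=tasks_fast)
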