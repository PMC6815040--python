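"""Simulator physics and cohort-generation contracts."""

import math

import numpy as np
import pytest

from exopark.config import CohortSpec, EffectMultipliers, TaskConfig
from exopark.features import count_hits, mean_hand_speed, stretch_torques
from exopark.synthetic import (
    bin_center_x,
    control_profile,
    generate_cohort,
    minimum_jerk_profile,
    pd_profile,
    simulate_object_hit_trial,
    simulate_stretch_trial,
    simulate_unloading_trial,
)

AMPLITUDE = math.radians(80.0)


def _ideal_profile(**kw):
    """Limb with no viscosity/stiffness/tone: pure inertia."""
    zero = {"right": 0.0, "left": 0.0}
    base = dict(viscosity=zero, stiffness=zero, tone=zero)
    base.update(kw)
    return control_profile(**base)


class TestMinimumJerk:
    @pytest.mark.parametrize(
        "T, expected_peak", [(0.6, 1.875 * AMPLITUDE / 0.6), (1.5, 1.875 * AMPLITUDE / 1.5)]
    )
    def test_closed_form_peak_velocity(self, T, expected_peak):
        _, omega = minimum_jerk_profile(math.radians(145), math.radians(65), T, 1000)
        assert np.max(np.abs(omega)) == pytest.approx(expected_peak, rel=1e-6)

    def test_boundary_conditions_and_single_peak(self):
        theta, omega = minimum_jerk_profile(0.2, 1.5, 0.8, 500)
        assert theta[0] == pytest.approx(0.2) and theta[-1] == pytest.approx(1.5)
        assert omega[0] == 0.0 and omega[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.argmax(np.abs(omega)) == omega.size // 2

    def test_degenerate_amplitude_is_constant(self):
        theta, omega = minimum_jerk_profile(1.0, 1.0, 0.5, 200)
        assert np.all(theta == 1.0) and np.all(omega == 0.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            minimum_jerk_profile(0.0, 1.0, 0.0, 100)


class TestStretchTrial:
    cfg = TaskConfig(sample_rate=1000)

    def test_impulse_momentum_for_pure_inertia(self):
        rec = simulate_stretch_trial(
            _ideal_profile(), self.cfg, "extension", 0.6, seed=1, viscous_feedforward=0.0
        )
        f = stretch_torques(rec)
        expected = _ideal_profile().inertia * f["peak_speed"]
        assert f["start_total"] == pytest.approx(expected, rel=0.01)
        assert f["end_total"] == pytest.approx(expected, rel=0.01)

    def test_static_tone_appears_as_constant_hold_torque(self):
        prof = control_profile(tone={"right": 0.05, "left": 0.05})
        rec = simulate_stretch_trial(prof, self.cfg, "flexion", 0.6, seed=2)
        assert stretch_torques(rec)["hold"] == pytest.approx(0.05, rel=0.05)

    def test_doubling_viscosity_raises_start_and_lowers_end_integral(self):
        f = {}
        for b in (0.05, 0.10):
            prof = _ideal_profile(viscosity={"right": b, "left": b})
            rec = simulate_stretch_trial(prof, self.cfg, "extension", 0.6, seed=3)
            f[b] = stretch_torques(rec)
        assert f[0.10]["start_total"] > f[0.05]["start_total"]
        assert f[0.10]["end_total"] < f[0.05]["end_total"]

    def test_measured_peak_speed_below_commanded_and_decreasing_in_rigidity(self):
        cmd_peak = 1.875 * AMPLITUDE / 0.6
        peaks = []
        for prof in (control_profile(), pd_profile(1.0)):
            rec = simulate_stretch_trial(prof, self.cfg, "extension", 0.6, seed=4)
            peaks.append(stretch_torques(rec)["peak_speed"])
        assert peaks[0] <= cmd_peak * 1.001
        assert peaks[0] >= 0.99 * cmd_peak  # healthy limb tracks >= 99%
        assert peaks[1] < peaks[0]

    def test_unstable_gains_raise_instead_of_diverging(self):
        with pytest.raises(RuntimeError, match="unstable"):
            simulate_stretch_trial(
                control_profile(), self.cfg, "extension", 0.6, seed=5,
                corrective_gains=(-80.0, -10.0),
            )

    def test_movement_time_must_be_configured(self):
        with pytest.raises(ValueError):
            simulate_stretch_trial(control_profile(), self.cfg, "flexion", 0.9, seed=6)


class TestObjectHitTrial:
    def test_pinned_paddles_only_reach_their_own_bin(self, tasks_fast):
        oh = tasks_fast.object_hit
        x0 = bin_center_x(oh, 0)
        prof = control_profile(max_hand_speed={"right": 0.0, "left": 0.0})
        rec = simulate_object_hit_trial(
            prof, tasks_fast, False, seed=1,
            home={"right": (x0, 0.2), "left": (x0 - 0.3, 0.45)},
        )
        bins = {e.payload["bin"] for e in rec.events_of("hit_target")}
        assert bins <= {0}
        assert len(rec.events_of("hit_target")) > 0

    def test_zero_error_rate_never_hits_distractors(self, tasks_fast):
        prof = control_profile(p_err=0.0)
        rec = simulate_object_hit_trial(prof, tasks_fast, True, seed=2)
        assert count_hits(rec)[1] == 0

    def test_spawn_speed_ramp_is_nondecreasing(self, tasks_fast):
        rec = simulate_object_hit_trial(control_profile(), tasks_fast, False, seed=3)
        spawns = sorted(rec.events_of("spawn"), key=lambda e: e.payload["object"])
        speeds = [e.payload["speed"] for e in spawns]
        assert all(b >= a for a, b in zip(speeds, speeds[1:]))
        assert len(spawns) == tasks_fast.object_hit.n_targets

    def test_slowed_profile_hits_fewer_targets(self, tasks_fast):
        worse = 0
        n = 8
        for seed in range(n):
            ctl = simulate_object_hit_trial(control_profile(), tasks_fast, False, seed=seed)
            slow = simulate_object_hit_trial(pd_profile(1.0), tasks_fast, False, seed=seed)
            worse += count_hits(slow)[0] < count_hits(ctl)[0]
        assert worse == n

    def test_avoid_mode_config_consistency(self, tasks_fast):
        # avoid mode needs distractors; plain mode must not have any
        no_distractors = tasks_fast.model_copy(
            update={"object_hit_avoid": tasks_fast.object_hit})
        with pytest.raises(ValueError):
            simulate_object_hit_trial(control_profile(), no_distractors, True, seed=1)
        with_distractors = tasks_fast.model_copy(
            update={"object_hit": tasks_fast.object_hit_avoid})
        with pytest.raises(ValueError):
            simulate_object_hit_trial(control_profile(), with_distractors, False, seed=1)


class TestUnloadingTrial:
    cfg = TaskConfig(sample_rate=1000)

    def test_undamped_passive_peak_is_twice_static_deflection(self):
        prof = _ideal_profile(stiffness={"right": 4.0, "left": 4.0})
        rec = simulate_unloading_trial(prof, self.cfg, 0.5, "elbow", True, seed=1,
                                       corrective=False)
        peak = np.max(np.abs(rec.theta_elbow))
        assert peak == pytest.approx(2 * 0.5 / 4.0, rel=0.02)

    def test_critically_damped_peak_approaches_static_deflection_from_below(self):
        k = 4.0
        b = 2 * math.sqrt(0.06 * k)
        prof = _ideal_profile(stiffness={"right": k, "left": k},
                              viscosity={"right": b, "left": b})
        rec = simulate_unloading_trial(prof, self.cfg, 0.5, "elbow", True, seed=1,
                                       corrective=False)
        peak = np.max(np.abs(rec.theta_elbow))
        assert peak < 0.5 / k
        assert peak > 0.9 * 0.5 / k

    def test_doubling_stiffness_reduces_hand_excursion(self):
        peaks = {}
        for k in (4.0, 8.0):
            prof = control_profile(stiffness={"right": k, "left": k})
            rec = simulate_unloading_trial(prof, self.cfg, 0.5, "elbow", True, seed=7)
            arm = rec.arm
            d = np.hypot(rec.hand_xy[arm][:, 0] - 0.0, rec.hand_xy[arm][:, 1] - 0.25)
            peaks[k] = d.max()
        assert peaks[8.0] < peaks[4.0]

    def test_load_magnitude_must_match_configuration(self):
        with pytest.raises(ValueError):
            simulate_unloading_trial(control_profile(), self.cfg, 0.3, "elbow", True, seed=1)


class TestGenerateCohort:
    def test_seeded_runs_are_byte_identical(self, tasks_tiny):
        spec = CohortSpec(n_controls=2, n_pd=2)
        a = generate_cohort(spec, 5, tasks_tiny)
        b = generate_cohort(spec, 5, tasks_tiny)
        assert a.manifest_json() == b.manifest_json()
        assert a.manifest_hash() == b.manifest_hash()

    def test_age_distribution_matches_spec(self, tasks_tiny):
        spec = CohortSpec(n_controls=1, n_pd=26)
        cohort = generate_cohort(spec, 9, tasks_tiny)
        ages = [s.age for s in cohort.subjects if s.group == "PD"]
        se = spec.age_sd / math.sqrt(len(ages))
        assert abs(np.mean(ages) - spec.age_mean) < 3 * se

    def test_pd_subjects_have_both_sessions(self, tasks_tiny):
        cohort = generate_cohort(CohortSpec(n_controls=1, n_pd=2), 3, tasks_tiny)
        sessions = {sid: set() for sid, _ in cohort.recordings}
        for sid, session in cohort.recordings:
            sessions[sid].add(session)
        for s in cohort.subjects:
            expected = {"off", "on"} if s.group == "PD" else {"baseline"}
            assert sessions[s.subject_id] == expected

    def test_null_multipliers_leave_groups_indistinguishable(self, tasks_tiny):
        null = EffectMultipliers()
        spec = CohortSpec(n_controls=10, n_pd=10, off=null, on=null, asymmetry=1.0)
        cohort = generate_cohort(spec, 13, tasks_tiny)
        speeds = {"control": [], "PD": []}
        for (sid, session), recs in cohort.recordings.items():
            if session == "on":
                continue
            grp = "PD" if sid.startswith("PD") else "control"
            oh = [r for r in recs if r.task == "object_hit"][0]
            speeds[grp].append(
                (mean_hand_speed(oh, "right") + mean_hand_speed(oh, "left")) / 2
            )
        from scipy import stats as sps

        p = sps.ttest_ind(speeds["PD"], speeds["control"]).pvalue
        assert p > 0.01

    def test_recording_invariants_hold_everywhere(self, small_cohort):
        for recs in small_cohort.recordings.values():
            for rec in recs:
                rec.validate()  # raises on any invariant violation
                times = [e.time for e in rec.events]
                assert times == sorted(times)
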