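"""Parameter extraction against analytic and brute-force oracles."""

import math

import numpy as np
import pytest

from exopark.config import TaskConfig
from exopark.features import (
    count_hits,
    extract_parameters,
    mean_hand_speed,
    movement_area,
    parameter_table,
    stretch_torques,
    total_torque_difference,
    unloading_features,
)
from exopark.recording import Event, TrialRecording
from exopark.synthetic import (
    control_profile,
    pd_profile,
    simulate_stretch_trial,
    simulate_unloading_trial,
)


def _recording(t, hand_xy, events=(), task="object_hit", arm="bilateral",
               torque=None, omega=None, theta=None, meta=None):
    n = t.size
    fs = 1.0 / (t[1] - t[0])
    zeros = np.zeros(n)
    return TrialRecording(
        task=task,
        arm=arm,
        t=t,
        theta_elbow=zeros if theta is None else theta,
        omega_elbow=zeros if omega is None else omega,
        hand_xy=hand_xy,
        robot_torque_elbow=zeros if torque is None else torque,
        events=list(events),
        sample_rate=fs,
        meta=meta or {},
    )


class TestMeanHandSpeed:
    def test_constant_speed_straight_line(self):
        t = np.arange(0, 5, 0.001)
        xy = np.column_stack([0.2 * t, np.zeros_like(t)])
        rec = _recording(t, {"right": xy, "left": np.zeros((t.size, 2))})
        assert mean_hand_speed(rec, "right") == pytest.approx(0.20, rel=1e-9)

    def test_stationary_hand_is_zero(self):
        t = np.arange(0, 2, 0.01)
        rec = _recording(t, {"right": np.full((t.size, 2), 0.3)})
        assert mean_hand_speed(rec, "right") == 0.0

    def test_circular_motion_matches_r_omega(self):
        t = np.arange(0, 4, 0.001)
        r, w = 0.1, 3.0
        xy = np.column_stack([r * np.cos(w * t), r * np.sin(w * t)])
        rec = _recording(t, {"right": xy})
        assert mean_hand_speed(rec, "right") == pytest.approx(r * w, rel=0.005)

    def test_too_few_samples_rejected(self):
        # a one-sample trajectory cannot be differentiated
        bad = TrialRecording.__new__(TrialRecording)  # bypass validation
        bad.hand_xy = {"right": np.zeros((1, 2))}
        bad.sample_rate = 100.0
        with pytest.raises(ValueError):
            mean_hand_speed(bad, "right")


class TestMovementArea:
    def test_square_perimeter_hull(self):
        n = 401  # grid lands exactly on the square's corners
        t = np.arange(n) * 0.01
        corners = np.array([[0, 0], [0.1, 0], [0.1, 0.1], [0, 0.1], [0, 0]])
        seg = np.linspace(0, 4, n) % 4
        idx = np.minimum(seg.astype(int), 3)
        frac = seg - idx
        xy = corners[idx] + frac[:, None] * (corners[idx + 1] - corners[idx])
        rec = _recording(t, {"right": xy, "left": np.full((n, 2), 0.3)})
        with pytest.warns(UserWarning, match="degenerate"):
            assert movement_area(rec) == pytest.approx(0.01, rel=1e-6)

    def test_stationary_hands_give_zero_with_warning(self):
        t = np.arange(0, 1, 0.01)
        rec = _recording(t, {"right": np.full((t.size, 2), 0.2)})
        with pytest.warns(UserWarning):
            assert movement_area(rec) == 0.0

    def test_polygon_vertices_match_shoelace_hull_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.random((40, 2))
        t = np.arange(pts.shape[0]) * 0.01
        rec = _recording(t, {"right": pts})
        # brute-force oracle: shoelace area over the hull found by angle sort
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        v = pts[hull.vertices]
        shoelace = 0.5 * abs(
            np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        )
        assert movement_area(rec, "right") == pytest.approx(shoelace, rel=1e-12)


class TestCountHits:
    def _rec_with_events(self, events):
        t = np.arange(0, 10, 0.01)
        return _recording(t, {"right": np.zeros((t.size, 2))}, events=events)

    def test_empty_log(self):
        assert count_hits(self._rec_with_events([])) == (0, 0)

    def test_mixed_hits_enumerated(self):
        ev = [Event(0.1 * (i + 1), "hit_target", {"object": i}) for i in range(3)]
        ev += [Event(1.0 + 0.1 * i, "hit_distractor", {"object": 10 + i}) for i in range(2)]
        assert count_hits(self._rec_with_events(ev)) == (3, 2)

    def test_large_constructed_log(self):
        ev = [Event(0.01 * (i + 1), "hit_target", {"object": i}) for i in range(179)]
        assert count_hits(self._rec_with_events(ev)) == (179, 0)

    def test_duplicate_object_hit_is_contract_violation(self):
        ev = [Event(0.1, "hit_target", {"object": 7}),
              Event(0.2, "hit_target", {"object": 7})]
        with pytest.raises(ValueError, match="duplicate"):
            count_hits(self._rec_with_events(ev))


class TestStretchTorques:
    cfg = TaskConfig(sample_rate=1000)

    def test_pure_inertia_closed_form(self):
        zero = {"right": 0.0, "left": 0.0}
        prof = control_profile(viscosity=zero, stiffness=zero, tone=zero)
        rec = simulate_stretch_trial(prof, self.cfg, "extension", 0.6, seed=1,
                                     viscous_feedforward=0.0)
        f = stretch_torques(rec)
        expected = prof.inertia * f["peak_speed"]  # impulse-momentum
        assert f["start_total"] == pytest.approx(expected, rel=0.01)
        assert f["difference"] == pytest.approx(0.0, abs=0.02 * expected)

    def test_viscous_limb_difference_is_b_dtheta(self):
        zero = {"right": 0.0, "left": 0.0}
        prof = control_profile(viscosity={"right": 0.1, "left": 0.1},
                               stiffness=zero, tone=zero)
        rec = simulate_stretch_trial(prof, self.cfg, "extension", 0.6, seed=1)
        f = stretch_torques(rec)
        assert f["difference"] == pytest.approx(0.1 * math.radians(80), rel=0.02)

    def test_constant_hold_torque_integrates_to_its_value(self):
        t = np.arange(0, 4, 0.001)
        n = t.size
        tau = np.full(n, 0.05)
        omega = np.zeros(n)
        i0, i1 = 3000, 3600
        omega[i0:i1] = np.sin(np.linspace(0, math.pi, i1 - i0))
        ev = [Event(3.0, "movement_start", {}), Event(3.599, "movement_end", {})]
        rec = _recording(t, {"right": np.zeros((n, 2))}, events=ev,
                         task="passive_stretch", arm="right", torque=tau, omega=omega)
        assert stretch_torques(rec)["hold"] == pytest.approx(0.05, rel=1e-3)

    def test_peak_at_boundary_is_an_error(self):
        t = np.arange(0, 4, 0.001)
        n = t.size
        omega = np.linspace(0, 1, n)  # monotone: peak at the segment end
        ev = [Event(3.0, "movement_start", {}), Event(3.9, "movement_end", {})]
        rec = _recording(t, {"right": np.zeros((n, 2))}, events=ev,
                         task="passive_stretch", arm="right", omega=omega)
        with pytest.raises(ValueError, match="boundary"):
            stretch_torques(rec)

    def test_insufficient_wait_is_an_error(self):
        t = np.arange(0, 2, 0.001)
        n = t.size
        omega = np.zeros(n)
        omega[1000:1500] = np.sin(np.linspace(0, math.pi, 500))
        ev = [Event(1.0, "movement_start", {}), Event(1.499, "movement_end", {})]
        rec = _recording(t, {"right": np.zeros((n, 2))}, events=ev,
                         task="passive_stretch", arm="right", omega=omega)
        with pytest.raises(ValueError, match="pre-movement"):
            stretch_torques(rec)

    def test_subsampling_changes_parameters_by_under_one_percent(self):
        prof = control_profile()
        rec = simulate_stretch_trial(prof, self.cfg, "extension", 0.6, seed=8)
        f_full = stretch_torques(rec)
        dec = TrialRecording(
            task=rec.task, arm=rec.arm, t=rec.t[::10],
            theta_elbow=rec.theta_elbow[::10], omega_elbow=rec.omega_elbow[::10],
            hand_xy={a: xy[::10] for a, xy in rec.hand_xy.items()},
            robot_torque_elbow=rec.robot_torque_elbow[::10],
            events=rec.events, sample_rate=rec.sample_rate / 10, meta=rec.meta,
        )
        f_dec = stretch_torques(dec)
        for key in ("start_total", "end_total", "hold", "peak_speed"):
            assert f_dec[key] == pytest.approx(f_full[key], rel=0.01)

    def test_difference_is_plain_arithmetic(self):
        assert total_torque_difference(0.262, 0.262) == 0.0
        assert total_torque_difference(0.30, 0.20) == pytest.approx(0.10)

    def test_rigid_profile_has_larger_difference(self):
        larger = 0
        n = 6
        for seed in range(n):
            fc = stretch_torques(simulate_stretch_trial(
                control_profile(), self.cfg, "extension", 0.6, seed=seed))
            fp = stretch_torques(simulate_stretch_trial(
                pd_profile(1.0), self.cfg, "extension", 0.6, seed=seed))
            larger += fp["difference"] > fc["difference"]
        assert larger == n


class TestUnloadingFeatures:
    cfg = TaskConfig(sample_rate=1000)

    def test_handbuilt_excursion_timing(self):
        t = np.arange(0, 3, 0.001)
        n = t.size
        center = np.array([0.0, 0.25])
        d = np.zeros(n)
        i_off = 1000
        i_pk = i_off + 180  # peak displacement 180 ms after release
        d[i_off:i_pk] = np.linspace(0, 0.05, i_pk - i_off)
        d[i_pk:] = np.linspace(0.05, 0.0, n - i_pk)
        xy = center + np.column_stack([d, np.zeros(n)])
        ev = [Event(0.0, "load_on", {}), Event(1.0, "load_off", {})]
        rec = _recording(t, {"right": xy}, events=ev, task="unloading", arm="right",
                         meta={"target_center": [0.0, 0.25], "target_radius": 0.01,
                               "stabilize_speed": 0.06})
        f = unloading_features(rec)
        assert f["deceleration_time"] == pytest.approx(180.0, abs=1.0)
        assert f["max_displacement"] == pytest.approx(0.05, rel=1e-9)
        assert f["endpoint_error"] == pytest.approx(0.0, abs=1e-12)

    def test_passive_spring_peak_matches_step_response(self):
        zero = {"right": 0.0, "left": 0.0}
        prof = control_profile(viscosity=zero, stiffness={"right": 4.0, "left": 4.0},
                               tone=zero)
        rec = simulate_unloading_trial(prof, self.cfg, 0.5, "elbow", True, seed=1,
                                       corrective=False)
        f = unloading_features(rec)
        lever = rec.meta["lever_arm"]
        assert f["max_displacement"] == pytest.approx(lever * 2 * 0.5 / 4.0, rel=0.02)

    def test_never_returning_hand_flags_missing_not_infinite(self):
        t = np.arange(0, 3, 0.001)
        n = t.size
        d = np.zeros(n)
        d[1000:] = np.linspace(0, 0.08, n - 1000)  # drifts away, never returns
        xy = np.column_stack([d, np.full(n, 0.25)])
        ev = [Event(1.0, "load_off", {})]
        rec = _recording(t, {"right": xy}, events=ev, task="unloading", arm="right",
                         meta={"target_center": [0.0, 0.25]})
        f = unloading_features(rec)
        assert math.isnan(f["return_time"]) and not math.isinf(f["return_time"])


class TestCohortExtraction:
    def test_tidy_table_shape_and_aggregation(self, small_cohort):
        tidy = extract_parameters(small_cohort)
        assert set(tidy.columns) == {"subject", "session", "task", "parameter",
                                     "arm", "value"}
        wide = parameter_table(tidy, arm="mean")
        # 8 controls + 8 PD x 2 sessions
        assert len(wide) == 8 + 16
        assert "oh_mean_hand_speed" in wide.columns

    def test_planted_effects_match_expected_directions(self, small_cohort):
        from exopark.pipeline import TABLE2_DIRECTIONS

        tidy = extract_parameters(small_cohort)
        wide = parameter_table(tidy, arm="mean")
        ctrl = wide.xs("baseline", level="session").mean()
        off = wide.xs("off", level="session").mean()
        for param, want in TABLE2_DIRECTIONS.items():
            assert np.sign(off[param] - ctrl[param]) == want, param

    def test_flexion_extension_averaging_is_order_invariant(self, small_cohort):
        key = next(k for k in small_cohort.recordings if k[1] == "off")
        recs = small_cohort.recordings[key]
        tidy_a = extract_parameters(type("C", (), {"recordings": {key: recs}}))
        tidy_b = extract_parameters(type("C", (), {"recordings": {key: recs[::-1]}}))
        a = tidy_a.sort_values(["parameter", "arm"])["value"].to_numpy()
        b = tidy_b.sort_values(["parameter", "arm"])["value"].to_numpy()
        assert np.allclose(a, b)
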