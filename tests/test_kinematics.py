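import math

import numpy as np
import pytest

from samarakin import (
    KinematicGroundTruth,
    SimulationConfig,
    TransientSpec,
    analyze_trajectory,
    angle_of_attack_series,
    cumulative_rotation_rate,
    detect_transition_times,
    estimate_angular_rates,
    estimate_coning_angle,
    estimate_descent_velocity,
    ground_truth_from_means,
    local_flow_angle_deg,
    locate_center_of_rotation,
    rolls_per_precession,
    simulate_descent,
    simulate_release_transient,
    time_to_first_roll,
)
from samarakin.trajectory import LandmarkTrajectory

from conftest import morphology_from_means

SPECIES = ("F_americana", "F_excelsior", "L_tulipifera")


# ----------------------------------------------------------------------
class TestParameterRecovery:
    @pytest.mark.parametrize("species", SPECIES)
    def test_noiseless_recovery_of_all_generator_values(self, species):
        """On noiseless 1 s tracks, every generator parameter comes back
        within 0.1% (rates, Vd) or 0.01 absolute (θ in deg)."""
        morph = morphology_from_means(species)
        truth = ground_truth_from_means(species, coning_angle_deg=5.0)
        traj = simulate_descent(morph, truth,
                                SimulationConfig(duration_s=1.0))
        omega_p, omega_r = estimate_angular_rates(traj)
        assert omega_p == pytest.approx(truth.omega_p, rel=1e-3)
        assert omega_r == pytest.approx(truth.omega_r, rel=1e-3)
        assert estimate_descent_velocity(traj) == pytest.approx(
            truth.Vd_cm_s, rel=1e-3)
        assert estimate_coning_angle(traj).mean_deg == pytest.approx(5.0,
                                                                     abs=0.01)

    def test_sign_recovery_follows_roll_direction(self, tulip_morph):
        for direction in (+1, -1):
            truth = ground_truth_from_means("L_tulipifera",
                                            roll_direction=direction)
            traj = simulate_descent(tulip_morph, truth,
                                    SimulationConfig(duration_s=0.3))
            omega_p, omega_r = estimate_angular_rates(traj)
            assert np.sign(omega_p) == direction
            assert np.sign(omega_r) == direction

    def test_frame_rate_invariance(self, tulip_morph):
        """Halving the frame rate to 500 fps moves the recovered rates
        by less than 0.1% on noiseless tracks."""
        truth = ground_truth_from_means("L_tulipifera")
        r1000 = estimate_angular_rates(simulate_descent(
            tulip_morph, truth, SimulationConfig(duration_s=0.5,
                                                 frame_rate=1000)))
        r500 = estimate_angular_rates(simulate_descent(
            tulip_morph, truth, SimulationConfig(duration_s=0.5,
                                                 frame_rate=500)))
        for a, b in zip(r1000, r500):
            assert a == pytest.approx(b, rel=1e-3)

    def test_noisy_rates_agree_with_cumulative_rotation_oracle(self,
                                                               tulip_morph):
        """With 0.05 cm tracking noise the phase-slope estimates agree
        with the frame-wise cumulative-rotation oracle within 1%."""
        truth = ground_truth_from_means("L_tulipifera")
        traj = simulate_descent(tulip_morph, truth,
                                SimulationConfig(duration_s=1.0,
                                                 noise_sd_cm=0.05,
                                                 rng_seed=13))
        omega_p, omega_r = estimate_angular_rates(traj)
        assert omega_r == pytest.approx(
            cumulative_rotation_rate(traj, "roll"), rel=0.01)
        assert omega_p == pytest.approx(
            cumulative_rotation_rate(traj, "precession"), rel=0.01)

    def test_noise_robustness_over_replicates(self, tulip_morph):
        """Rate estimates stay within 1% of truth across noisy replicates."""
        truth = ground_truth_from_means("L_tulipifera")
        for seed in range(20):
            traj = simulate_descent(
                tulip_morph, truth,
                SimulationConfig(duration_s=1.0, noise_sd_cm=0.05,
                                 rng_seed=1000 + seed))
            omega_p, omega_r = estimate_angular_rates(traj)
            assert omega_p == pytest.approx(truth.omega_p, rel=0.01)
            assert omega_r == pytest.approx(truth.omega_r, rel=0.01)


# ----------------------------------------------------------------------
class TestDescentVelocity:
    def test_stationary_track_gives_zero(self, tulip_morph):
        truth = KinematicGroundTruth(Vd_cm_s=0.0, omega_p=0.0, omega_r=0.0)
        traj = simulate_descent(tulip_morph, truth,
                                SimulationConfig(duration_s=0.2))
        assert estimate_descent_velocity(traj) == pytest.approx(0.0, abs=1e-12)

    def test_pure_line_descent(self, tulip_morph):
        """A non-rotating body on z = −200·t recovers 200 cm/s."""
        truth = KinematicGroundTruth(Vd_cm_s=200.0, omega_p=0.0, omega_r=0.0)
        vd = estimate_descent_velocity(simulate_descent(
            tulip_morph, truth, SimulationConfig(duration_s=0.2)))
        assert vd == pytest.approx(200.0, rel=1e-9)

    def test_rejects_too_short_record(self, tulip_morph):
        with pytest.raises(ValueError):
            LandmarkTrajectory(frame_rate=1000.0, t=np.array([0.0]),
                               seed_tip=np.zeros((1, 3)),
                               wingtip=np.ones((1, 3)),
                               chord_left=np.zeros((1, 3)),
                               chord_right=np.ones((1, 3)))


# ----------------------------------------------------------------------
class TestConingAngle:
    def test_horizontal_span_gives_zero(self, tulip_track):
        traj, _ = tulip_track
        assert estimate_coning_angle(traj).mean_deg == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_mean_of_linear_drift_is_midpoint(self, tulip_morph):
        """A 0→5° linear coning ramp averages to 2.5°."""
        truth = ground_truth_from_means("L_tulipifera")
        traj = simulate_descent(tulip_morph, truth,
                                SimulationConfig(duration_s=0.5))
        # impose the ramp by tilting the span vector directly
        theta = np.linspace(0.0, np.deg2rad(5.0), traj.n_frames)
        span = traj.span_vectors()
        length = np.linalg.norm(span, axis=1)
        horiz = span.copy()
        horiz[:, 2] = 0.0
        horiz /= np.linalg.norm(horiz, axis=1, keepdims=True)
        tilted = (horiz * (length * np.cos(theta))[:, None])
        tilted[:, 2] = length * np.sin(theta)
        traj2 = LandmarkTrajectory(
            frame_rate=traj.frame_rate, t=traj.t, seed_tip=traj.seed_tip,
            wingtip=traj.seed_tip + tilted, chord_left=traj.chord_left,
            chord_right=traj.chord_right)
        res = estimate_coning_angle(traj2)
        assert res.mean_deg == pytest.approx(2.5, abs=0.01)
        assert res.series_deg.shape == (traj.n_frames,)


# ----------------------------------------------------------------------
class TestCenterOfRotation:
    @pytest.mark.parametrize("cor", [0.3, 0.5])
    def test_recovery_at_zero_precession_radius(self, tulip_morph, cor):
        truth = ground_truth_from_means("L_tulipifera", cor_fraction=cor,
                                        precession_radius_cm=0.0)
        traj = simulate_descent(tulip_morph, truth,
                                SimulationConfig(duration_s=0.5))
        assert locate_center_of_rotation(traj) == pytest.approx(cor, abs=0.01)

    def test_matches_exhaustive_grid_search(self, tulip_morph):
        """The refined estimate agrees with a 10⁻³-resolution brute-force
        scan of the same objective."""
        truth = ground_truth_from_means("L_tulipifera", cor_fraction=0.3,
                                        precession_radius_cm=0.0)
        traj = simulate_descent(tulip_morph, truth,
                                SimulationConfig(duration_s=0.5))
        s_grid = np.arange(0.0, 1.0001, 1e-3)
        seed_xy = traj.seed_tip[:, :2]
        span_xy = traj.span_vectors()[:, :2]
        J = [np.var(seed_xy[:, 0] + s * span_xy[:, 0])
             + np.var(seed_xy[:, 1] + s * span_xy[:, 1]) for s in s_grid]
        brute = s_grid[int(np.argmin(J))]
        assert locate_center_of_rotation(traj) == pytest.approx(brute,
                                                                abs=1e-3)

    def test_rigid_translation_flagged_undefined(self, tulip_morph):
        truth = KinematicGroundTruth(Vd_cm_s=100.0, omega_p=0.0, omega_r=0.0)
        traj = simulate_descent(tulip_morph, truth,
                                SimulationConfig(duration_s=0.2))
        assert math.isnan(locate_center_of_rotation(traj))


# ----------------------------------------------------------------------
class TestAngleOfAttack:
    def test_closed_form_flow_angle(self):
        """Flow angle at the 0.75-span station for Vd = 1.31 m/s,
        S = 3.9 cm, ωp = 93.5 rad/s is arctan(1.31/(0.75·0.039·93.5))."""
        assert local_flow_angle_deg(131.0, 3.9, 93.5) == pytest.approx(25.6,
                                                                       abs=0.05)

    def test_bounded_and_two_folds_per_roll_cycle(self, tulip_track):
        traj, truth = tulip_track
        alpha = angle_of_attack_series(traj, truth.Vd_cm_s,
                                       truth.roll_direction * truth.omega_p)
        assert alpha.shape == (traj.n_frames,)
        assert np.all(alpha > -90.0) and np.all(alpha <= 90.0)
        jumps = int(np.sum(np.abs(np.diff(alpha)) > 90.0))
        cycles = truth.omega_r * traj.duration / (2 * math.pi)
        assert abs(jumps - 2 * cycles) <= 1.0

    def test_chord_parallel_and_perpendicular_to_flow(self, tulip_morph):
        """Pure vertical flow: a vertical chord reads 0°, horizontal 90°."""
        n = 10
        t = np.arange(n) / 1000.0
        base = np.zeros((n, 3))
        span = np.tile([3.6, 0.0, 0.0], (n, 1))
        vert = np.tile([0.0, 0.0, 0.4], (n, 1))
        horiz = np.tile([0.0, 0.4, 0.0], (n, 1))
        parallel = LandmarkTrajectory(frame_rate=1000.0, t=t, seed_tip=base,
                                      wingtip=base + span,
                                      chord_left=base + span / 2 - vert,
                                      chord_right=base + span / 2 + vert)
        perp = LandmarkTrajectory(frame_rate=1000.0, t=t, seed_tip=base,
                                  wingtip=base + span,
                                  chord_left=base + span / 2 - horiz,
                                  chord_right=base + span / 2 + horiz)
        a_par = angle_of_attack_series(parallel, 150.0, 0.0)
        a_perp = angle_of_attack_series(perp, 150.0, 0.0)
        assert np.allclose(np.abs(a_par), 0.0, atol=1e-9)
        assert np.allclose(a_perp, 90.0, atol=1e-9)

    def test_zero_flow_rejected(self, tulip_track):
        traj, _ = tulip_track
        with pytest.raises(ValueError, match="zero flow"):
            angle_of_attack_series(traj, 0.0, 0.0)


# ----------------------------------------------------------------------
class TestRollsPerPrecession:
    @pytest.mark.parametrize("wr,wp,expected", [
        (442.6, 79.6, 5.56),    # F. americana species means
        (617.6, 119.3, 5.18),   # F. excelsior species means
        (100.0, 100.0, 1.0),
    ])
    def test_ratio(self, wr, wp, expected):
        assert rolls_per_precession(wr, wp) == pytest.approx(expected,
                                                             abs=0.005)

    def test_zero_precession_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rolls_per_precession(400.0, 0.0)


# ----------------------------------------------------------------------
class TestTransitionTimes:
    def _transient_track(self, morph, truth, tr, duration=0.6):
        cfg = SimulationConfig(duration_s=duration, frame_rate=1000.0,
                               frame="tunnel", transient=tr)
        return simulate_release_transient(morph, truth, cfg)

    def test_steady_tunnel_gives_roll_period_and_zero_tp(self, tulip_morph):
        truth = ground_truth_from_means("L_tulipifera")
        traj = simulate_descent(tulip_morph, truth,
                                SimulationConfig(duration_s=0.5,
                                                 frame="tunnel"))
        ev = detect_transition_times(traj, truth.Vd_cm_s)
        assert ev.roll_reached and ev.precession_reached
        assert ev.t_r == pytest.approx(2 * math.pi / truth.omega_r, rel=1e-6)
        assert ev.t_p == pytest.approx(0.0, abs=1e-9)

    def test_first_roll_matches_phase_integral_oracle(self, tulip_morph):
        truth = ground_truth_from_means("L_tulipifera",
                                        omega_r=503.5)
        tr = TransientSpec(roll_onset_delay_s=0.047,
                           precession_onset_delay_s=0.12,
                           roll_tau_s=0.001, precession_tau_s=0.04)
        traj = self._transient_track(tulip_morph, truth, tr)
        ev = detect_transition_times(traj, truth.Vd_cm_s)
        assert ev.t_r == pytest.approx(time_to_first_roll(503.5, tr),
                                       abs=1e-3)
        assert ev.t_r == pytest.approx(0.047 + 2 * math.pi / 503.5, abs=2e-3)

    def test_truncated_record_flags_tp_not_reached(self, tulip_morph):
        truth = ground_truth_from_means("L_tulipifera")
        tr = TransientSpec(roll_onset_delay_s=0.02,
                           precession_onset_delay_s=0.15,
                           roll_tau_s=0.004, precession_tau_s=0.05)
        traj = self._transient_track(tulip_morph, truth, tr, duration=0.2)
        ev = detect_transition_times(traj, truth.Vd_cm_s)
        assert ev.roll_reached
        assert not ev.precession_reached and math.isnan(ev.t_p)

    def test_free_fall_frame_flagged_not_exception(self, tulip_track):
        traj, truth = tulip_track
        ev = detect_transition_times(traj, truth.Vd_cm_s)
        assert not ev.precession_reached

    def test_monotone_in_roll_onset_delay(self, tulip_morph):
        """Increasing the roll-onset delay never decreases t_r."""
        truth = ground_truth_from_means("L_tulipifera")
        last = -1.0
        for d_r in (0.0, 0.05, 0.1, 0.15, 0.2):
            tr = TransientSpec(roll_onset_delay_s=d_r,
                               precession_onset_delay_s=d_r + 0.05,
                               roll_tau_s=0.004, precession_tau_s=0.04)
            traj = self._transient_track(tulip_morph, truth, tr, duration=0.8)
            ev = detect_transition_times(traj, truth.Vd_cm_s)
            assert ev.roll_reached
            assert ev.t_r >= last
            last = ev.t_r

    def test_orientation_five_never_levitates(self, tulip_morph):
        truth = ground_truth_from_means("L_tulipifera")
        tr = TransientSpec.from_orientation(5)
        traj = self._transient_track(tulip_morph, truth, tr, duration=0.8)
        ev = detect_transition_times(traj, truth.Vd_cm_s)
        assert ev.roll_reached and not ev.precession_reached


# ----------------------------------------------------------------------
def test_analyze_trajectory_bundles_everything(americana_track):
    traj, truth = americana_track
    est = analyze_trajectory(traj)
    assert est.Vd_cm_s == pytest.approx(131.0, rel=1e-3)
    assert est.omega_p == pytest.approx(79.6, rel=1e-3)
    assert est.omega_r == pytest.approx(442.6, rel=1e-3)
    assert est.roll_sign == est.precession_sign == truth.roll_direction
    assert est.roll_per_precession == pytest.approx(442.6 / 79.6, rel=1e-3)
    assert est.alpha_deg.shape == (traj.n_frames,)
    assert est.diagnostics["precession_cycles"] > 1
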