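"""Generator contracts: templates, forward kinematics, GRF, corruption."""

import numpy as np
import pytest

from gaitval import (
    GaitProfile,
    JOINTS,
    SIDES,
    angle_templates,
    corrupt,
    forward_kinematics,
    joint_angles,
    make_trial,
    parameter_targets,
    synth_grf,
    true_angle_waveforms,
)
from gaitval.synthetic import crossing_frames, trial_duration
from gaitval.types import kp_index

DENSE_T = np.linspace(0, 1, 20001)


class TestAngleTemplates:
    def test_extrema_hit_profile_amplitudes(self):
        profile = GaitProfile(knee_swing_peak_flex=60.0)
        curves = angle_templates(profile, DENSE_T)
        assert np.max(curves["knee"]) == pytest.approx(60.0, abs=0.1)
        assert np.max(curves["hip"]) == pytest.approx(profile.hip_peak_flex, abs=0.1)
        assert np.min(curves["hip"]) == pytest.approx(-profile.hip_peak_ext, abs=0.1)
        assert np.max(curves["ankle"]) == pytest.approx(profile.ankle_peak_dorsi, abs=0.1)
        assert np.min(curves["ankle"]) == pytest.approx(-profile.ankle_peak_plantar, abs=0.1)

    def test_zero_amplitudes_give_zero_waveforms(self):
        profile = GaitProfile(
            hip_peak_flex=0, hip_peak_ext=0, knee_stance_peak_flex=0,
            knee_swing_peak_flex=0, ankle_peak_dorsi=0, ankle_peak_plantar=0,
        )
        curves = angle_templates(profile, DENSE_T)
        for joint in JOINTS:
            np.testing.assert_array_equal(curves[joint], 0.0)

    def test_periodic_boundary(self):
        curves = angle_templates(GaitProfile(), np.array([0.0, 1.0]))
        for joint in JOINTS:
            assert curves[joint][0] == pytest.approx(curves[joint][1], abs=1e-12)

    def test_out_of_range_phase_rejected(self):
        with pytest.raises(ValueError):
            angle_templates(GaitProfile(), np.array([-0.1, 0.5]))

    def test_non_finite_amplitude_rejected(self):
        with pytest.raises(ValueError):
            GaitProfile(hip_peak_flex=float("nan"))

    def test_smoothness_no_jumps(self):
        curves = angle_templates(GaitProfile(), DENSE_T)
        dt = DENSE_T[1] - DENSE_T[0]
        for joint in JOINTS:
            # bounded derivative: no discontinuities at lobe edges
            assert np.max(np.abs(np.diff(curves[joint]) / dt)) < 2000


class TestForwardKinematics:
    def test_zero_pose_gives_straight_collinear_legs(self):
        profile = GaitProfile(
            hip_peak_flex=0, hip_peak_ext=0, knee_stance_peak_flex=0,
            knee_swing_peak_flex=0, ankle_peak_dorsi=0, ankle_peak_plantar=0,
            n_cycles=1,
        )
        trial = forward_kinematics(profile)
        for p in ("R", "L"):
            hip = trial.reference.xy[:, kp_index(p + "Hip")]
            knee = trial.reference.xy[:, kp_index(p + "Knee")]
            ankle = trial.reference.xy[:, kp_index(p + "Ankle")]
            cross = (knee - hip)[:, 0] * (ankle - hip)[:, 1] - (knee - hip)[:, 1] * (ankle - hip)[:, 0]
            np.testing.assert_allclose(cross, 0.0, atol=1e-6)

    def test_roundtrip_recovers_true_angles(self, noiseless_trial):
        angles = joint_angles(noiseless_trial.pose)
        for side in SIDES:
            for joint in JOINTS:
                err = np.abs(angles[(side, joint)].values - noiseless_trial.true_angles[(side, joint)])
                assert np.nanmax(err) < 1e-9

    def test_same_seed_is_bitwise_identical(self):
        profile = GaitProfile(seed=7, noise_sd=2.0, dropout_prob_crossing=0.3, n_cycles=2)
        a, b = make_trial(profile), make_trial(profile)
        np.testing.assert_array_equal(a.pose.xy, b.pose.xy)
        np.testing.assert_array_equal(a.pose.confidence, b.pose.confidence)
        np.testing.assert_array_equal(a.grf_right.fz, b.grf_right.fz)

    def test_left_is_right_shifted_half_cycle(self, default_profile):
        t, angles = true_angle_waveforms(default_profile)
        frames_per_cycle = default_profile.cycle_duration * default_profile.sample_rate_video
        shift = int(round(frames_per_cycle / 2))
        assert shift == frames_per_cycle / 2  # exact for the default rates
        for joint in JOINTS:
            r, l = angles[("right", joint)], angles[("left", joint)]
            np.testing.assert_allclose(l[shift:], r[:-shift], atol=1e-9)

    def test_nonpositive_segment_length_rejected(self):
        with pytest.raises(ValueError):
            GaitProfile(segment_lengths={"trunk": 0.5, "thigh": -0.1, "shank": 0.4, "foot": 0.2})


class TestSynthGrf:
    def test_swing_phase_is_exactly_zero(self, default_profile):
        from gaitval.synthetic import _side_phase

        grf = synth_grf(default_profile, "right")
        phase = _side_phase(default_profile, grf.timestamps, "right")
        swing = phase >= default_profile.stance_fraction
        assert swing.any()
        assert np.all(grf.fz[swing] == 0.0)

    def test_crosses_threshold_at_declared_contact(self, noiseless_trial):
        for side, grf in (("right", noiseless_trial.grf_right), ("left", noiseless_trial.grf_left)):
            for ic in noiseless_trial.true_events[side]:
                assert grf.fz[ic] > 20.0
                assert np.all(grf.fz[max(0, ic - 60) : ic] <= 20.0)

    def test_peak_scales_linearly_with_body_weight(self):
        lo = synth_grf(GaitProfile(body_weight_n=500), "right")
        hi = synth_grf(GaitProfile(body_weight_n=1000), "right")
        assert np.max(hi.fz) == pytest.approx(2 * np.max(lo.fz), rel=1e-12)
        assert np.max(lo.fz) == pytest.approx(1.05 * 500, rel=0.02)  # near body weight

    def test_left_offset_half_cycle(self, default_profile):
        r = synth_grf(default_profile, "right")
        l = synth_grf(default_profile, "left")
        half = int(round(default_profile.cycle_duration * default_profile.sample_rate_force / 2))
        np.testing.assert_allclose(l.fz[half:], r.fz[:-half], atol=1e-9)


class TestCorrupt:
    def test_identity_when_clean(self, noiseless_trial):
        out = corrupt(noiseless_trial.pose, 0.0, 0.0, seed=3)
        np.testing.assert_array_equal(out.xy, noiseless_trial.pose.xy)
        np.testing.assert_array_equal(out.confidence, noiseless_trial.pose.confidence)

    def test_noise_rms_matches_requested_sd(self):
        # >= 1e4 frames: 75 cycles of 1.1 s at 120 Hz
        profile = GaitProfile(n_cycles=75, seed=5)
        trial = forward_kinematics(profile)
        assert trial.pose.n_frames >= 10_000
        noisy = corrupt(trial.pose, noise_sd=2.0, dropout_prob_crossing=0.0, seed=5)
        rms = np.sqrt(np.mean((noisy.xy - trial.pose.xy) ** 2))
        assert rms == pytest.approx(2.0, rel=0.10)

    def test_full_dropout_in_crossing_windows(self, noiseless_trial):
        pose = noiseless_trial.pose
        out = corrupt(pose, 0.0, 1.0, seed=0, crossing_threshold_px=20.0)
        crossing = crossing_frames(pose, 20.0)
        assert crossing.any()
        for name in ("LKnee", "LAnkle", "LBigToe", "LHeel"):
            assert np.all(out.confidence[crossing, kp_index(name)] == 0.0)
        # camera-side limb is never dropped
        for name in ("RKnee", "RAnkle", "RBigToe", "RHeel"):
            assert np.all(out.confidence[:, kp_index(name)] > 0)

    def test_negative_noise_rejected(self, noiseless_trial):
        with pytest.raises(ValueError):
            corrupt(noiseless_trial.pose, -1.0, 0.0, seed=0)


def test_parameter_targets_match_template_extrema():
    profile = GaitProfile()
    targets = parameter_targets(profile)
    assert targets["knee_swing_peak_flexion"] == pytest.approx(profile.knee_swing_peak_flex, abs=1e-6)
    assert targets["ankle_excursion"] == pytest.approx(
        profile.ankle_peak_dorsi + profile.ankle_peak_plantar, abs=1e-6
    )
    assert targets["hip_excursion"] == pytest.approx(
        profile.hip_peak_flex + profile.hip_peak_ext, abs=1e-6
    )


def test_trial_duration_covers_n_cycles_per_side(default_profile):
    assert trial_duration(default_profile) == pytest.approx(
        (default_profile.n_cycles + 1) * default_profile.cycle_duration
    )
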