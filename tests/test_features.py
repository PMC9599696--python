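"""Kinematic features: smoothness metrics, angles, per-part features."""

import numpy as np
import pytest
from scipy.integrate import quad

from fmascore import (HandSequence, GraspRecording, Segment,
                      SHOULDER_ELBOW_FEATURES, coordination_features,
                      dimensionless_jerk, endpoint_features, grasp_features,
                      hand_features, ijci, joint_angles,
                      shoulder_elbow_vector, sparc, trunk_compensation,
                      wrist_hand_features)
from fmascore.exceptions import DegenerateInputError, ValidationError
from fmascore.io import HAND_CHANNELS
from tests.conftest import make_skeleton


def minjerk_speed(fps, duration=1.0, peak_scale=1.0):
    t = np.linspace(0, 1, int(fps * duration) + 1)
    return peak_scale * 30 * t ** 2 * (1 - t) ** 2


def sparc_oracle(v, fs, fc=10.0, amp_th=0.05):
    """Independent SPARC oracle: full FFT, explicit arc-length loop."""
    v = np.asarray(v, dtype=float)
    nfft = max(4096, int(2 ** (np.ceil(np.log2(len(v))) + 4)))
    spec = np.abs(np.fft.fft(v, nfft))[: nfft // 2 + 1]
    freqs = np.arange(nfft // 2 + 1) * (fs / nfft)
    spec = spec / spec.max()
    keep = freqs <= fc
    freqs, spec = freqs[keep], spec[keep]
    idx = [i for i, m in enumerate(spec) if m >= amp_th]
    lo, hi = idx[0], idx[-1]
    freqs, spec = freqs[lo:hi + 1], spec[lo:hi + 1]
    span = freqs[-1] - freqs[0]
    total = 0.0
    for i in range(len(freqs) - 1):
        df = (freqs[i + 1] - freqs[i]) / span
        dm = spec[i + 1] - spec[i]
        total += np.hypot(df, dm)
    return -total


class TestSparc:
    def test_amplitude_invariance(self, rng):
        v = np.abs(rng.normal(1, 0.3, 128))
        # power-of-two scalings commute bit-exactly with the FFT
        assert sparc(v, 100.0) == sparc(2.0 * v, 100.0)
        assert sparc(v, 100.0) == sparc(0.125 * v, 100.0)
        assert sparc(v, 100.0) == pytest.approx(sparc(0.1 * v, 100.0),
                                                abs=1e-10)

    def test_matches_fft_oracle_on_gaussian_pulse(self):
        t = np.linspace(0, 1, 101)
        v = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        assert sparc(v, 100.0) == pytest.approx(sparc_oracle(v, 100.0),
                                                abs=1e-6)

    def test_matches_fft_oracle_on_random_profiles(self, rng):
        for _ in range(10):
            v = np.abs(rng.normal(1, 0.4, int(rng.integers(50, 300))))
            assert sparc(v, 60.0) == pytest.approx(sparc_oracle(v, 60.0),
                                                   abs=1e-6)

    def test_segmented_profile_is_less_smooth(self):
        fps = 100.0
        single = minjerk_speed(fps, duration=1.0)
        half = minjerk_speed(fps, duration=0.5)
        two = np.concatenate([half, half])[: len(single)]
        assert sparc(two, fps) < sparc(single, fps)

    def test_all_zero_speed_rejected(self):
        with pytest.raises(DegenerateInputError):
            sparc(np.zeros(64), 100.0)

    def test_always_non_positive(self, rng):
        for _ in range(5):
            v = np.abs(rng.normal(1, 0.5, 100))
            assert sparc(v, 100.0) <= 0


class TestDimensionlessJerk:
    def test_scale_invariance_within_one_percent(self):
        fps = 200.0
        base = dimensionless_jerk(minjerk_speed(fps), fps)
        # amplitude scaling
        assert dimensionless_jerk(3.7 * minjerk_speed(fps), fps) == \
            pytest.approx(base, rel=1e-12)
        # temporal scaling: same profile stretched to 2 s
        t2 = np.linspace(0, 1, int(2 * fps) + 1)
        stretched = 30 * t2 ** 2 * (1 - t2) ** 2
        assert dimensionless_jerk(stretched, fps) == \
            pytest.approx(base, rel=0.01)

    def test_matches_quadrature_oracle_on_minimum_jerk(self):
        fps = 200.0
        # d2v/dt2 of v(t) = 30 t^2 (1-t)^2 over unit duration
        integral = quad(lambda t: (30 * (2 - 12 * t + 12 * t ** 2)) ** 2,
                        0, 1)[0]
        exact = -integral / 1.875 ** 2
        assert dimensionless_jerk(minjerk_speed(fps), fps) == \
            pytest.approx(exact, rel=0.005)

    def test_matches_quadrature_oracle_on_gaussian(self):
        fps, sig = 500.0, 0.1

        def d2v(t):
            z = (t - 0.5) / sig
            return np.exp(-0.5 * z ** 2) * (z ** 2 - 1) / sig ** 2

        integral = quad(lambda t: d2v(t) ** 2, 0, 1, limit=200)[0]
        t = np.linspace(0, 1, int(fps) + 1)
        v = np.exp(-0.5 * ((t - 0.5) / sig) ** 2)
        assert dimensionless_jerk(v, fps) == \
            pytest.approx(-integral, rel=0.005)

    def test_ripple_makes_jerk_more_negative(self):
        fps = 200.0
        v = minjerk_speed(fps)
        t = np.linspace(0, 1, len(v))
        rippled = v + 0.1 * v.max() * np.sin(2 * np.pi * 10 * t)
        rippled = np.clip(rippled, 0, None)
        assert dimensionless_jerk(rippled, fps) < dimensionless_jerk(v, fps)

    def test_zero_peak_speed_rejected(self):
        with pytest.raises(DegenerateInputError):
            dimensionless_jerk(np.zeros(10), 100.0)


class TestEndpointFeatures:
    def _line_sequence(self):
        # wrist moves (0,0,0) -> (1,0,0) in 11 uniform frames over 1 s
        return make_skeleton(
            lambda t: {"wrist_l": (t / 10.0, 0.0, 0.0)},
            n_frames=11, fps=10.0)

    def test_straight_line_path_length(self):
        seq = self._line_sequence()
        out = endpoint_features(seq, Segment(0, 10), "wrist_l")
        assert out["path_length"] == pytest.approx(1.0, abs=1e-12)
        assert out["v_mean"] == pytest.approx(1.0, abs=1e-9)
        assert out["v_max"] == pytest.approx(1.0, abs=1e-9)
        assert out["v_var"] == pytest.approx(0.0, abs=1e-9)

    def test_stationary_endpoint(self, static_skeleton):
        out = endpoint_features(static_skeleton, Segment(0, 59), "wrist_l")
        assert out["path_length"] == 0.0
        assert out["v_max"] == pytest.approx(0.0, abs=1e-12)

    def test_path_length_bounds_displacement(self, rng):
        seq = make_skeleton(
            lambda t: {"wrist_l": tuple(0.02 * np.sin([t / 3, t / 5, t / 7]))},
            n_frames=50)
        out = endpoint_features(seq, Segment(0, 49), "wrist_l")
        disp = np.linalg.norm(seq.joint("wrist_l")[-1]
                              - seq.joint("wrist_l")[0])
        assert out["path_length"] >= disp - 1e-12

    def test_too_few_frames_rejected(self, static_skeleton):
        with pytest.raises(ValidationError):
            endpoint_features(static_skeleton, Segment(0, 1), "wrist_l")


class TestJointAngles:
    def _arm_pose(self, elbow_off, wrist_off):
        """Left shoulder at (0.19, 1.0, 0); trunk upright."""
        def fn(t):
            return {
                "neck": (0.0, 1.05, 0.0),
                "mid_hip": (0.0, 0.55, 0.0),
                "shoulder_l": (0.19, 1.0, 0.0),
                "shoulder_r": (-0.19, 1.0, 0.0),
                "elbow_l": tuple(np.array([0.19, 1.0, 0.0]) + elbow_off),
                "wrist_l": tuple(np.array([0.19, 1.0, 0.0]) + elbow_off
                                 + wrist_off),
            }
        return make_skeleton(fn, n_frames=5)

    def test_extended_arm_has_zero_elbow_flexion(self):
        seq = self._arm_pose(np.array([0, -0.29, 0]), np.array([0, -0.26, 0]))
        angles = joint_angles(seq, "left")
        assert np.allclose(angles["elbow_flexion"], 0.0, atol=1e-6)

    def test_perpendicular_forearm_is_90_degrees(self):
        seq = self._arm_pose(np.array([0, -0.29, 0]), np.array([0, 0, 0.26]))
        angles = joint_angles(seq, "left")
        assert np.allclose(angles["elbow_flexion"], 90.0, atol=1e-6)

    def test_hanging_arm_reference_pose(self):
        seq = self._arm_pose(np.array([0, -0.29, 0]), np.array([0, 0, 0.26]))
        angles = joint_angles(seq, "left")
        assert np.allclose(angles["shoulder_flexion"], 0.0, atol=1e-6)
        assert np.allclose(angles["shoulder_adduction"], 0.0, atol=1e-6)

    def test_forward_arm_is_90_flexion(self):
        seq = self._arm_pose(np.array([0, 0, 0.29]), np.array([0, 0.05, 0.26]))
        angles = joint_angles(seq, "left")
        assert np.allclose(angles["shoulder_flexion"], 90.0, atol=1e-6)

    def test_abducted_arm_is_90_adduction_angle(self):
        seq = self._arm_pose(np.array([0.29, 0, 0]), np.array([0.26, 0, 0.05]))
        angles = joint_angles(seq, "left")
        assert np.allclose(angles["shoulder_adduction"], 90.0, atol=1e-6)

    def test_degenerate_limb_vector_rejected(self):
        seq = self._arm_pose(np.zeros(3), np.array([0, -0.26, 0]))
        with pytest.raises(ValidationError, match="degenerate"):
            joint_angles(seq, "left")


class TestAngularFeatures:
    def test_linear_ramp(self):
        from fmascore.features import angular_features

        ramp = np.linspace(0, 90, 31)            # 1 s at 30 fps
        out = angular_features(ramp, Segment(0, 30), 30.0)
        assert out["rom"] == pytest.approx(90.0)
        assert out["angle_max"] == pytest.approx(90.0)
        assert out["angle_min"] == pytest.approx(0.0)
        assert out["angvel_mean"] == pytest.approx(90.0, rel=1e-9)

    def test_constant_angle(self):
        from fmascore.features import angular_features

        out = angular_features(np.full(20, 45.0), Segment(0, 19), 30.0)
        assert out["rom"] == 0.0
        assert out["angvel_max"] == 0.0
        assert out["angvel_var"] == 0.0

    def test_sinusoid_matches_brute_force(self, rng):
        from fmascore.features import angular_features

        fps = 30.0
        a = 40 * np.sin(np.linspace(0, 4 * np.pi, 120)) + rng.normal(0, 1, 120)
        seg = Segment(10, 100)
        out = angular_features(a, seg, fps)
        win = a[10:101]
        vel = np.gradient(win, 1 / fps, edge_order=2)
        assert out["rom"] == pytest.approx(win.max() - win.min(), abs=1e-6)
        assert out["angvel_max"] == pytest.approx(np.abs(vel).max(), abs=1e-6)
        assert out["angvel_mean"] == pytest.approx(np.abs(vel).mean(),
                                                   abs=1e-6)
        assert out["angvel_var"] == pytest.approx(vel.var(), abs=1e-6)


class TestIjci:
    def test_perfect_linear_relation(self):
        sh = np.linspace(0, 90, 50)
        assert ijci(sh, 0.5 * sh + 10.0) == pytest.approx(1.0)

    def test_perfect_negative_relation(self):
        sh = np.linspace(0, 90, 50)
        assert ijci(sh, -sh) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert ijci(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            ijci(np.full(10, 5.0), np.arange(10.0))


class TestTrunkCompensation:
    def test_stationary_trunk(self, static_skeleton):
        out = trunk_compensation(static_skeleton, Segment(0, 59), "left")
        assert out["trunk_compensation"] == 0.0

    def test_planted_forward_lean(self):
        seq = make_skeleton(
            lambda t: {
                "shoulder_l": (0.19, 1.0, 0.05 * min(t / 30, 1.0)),
                "shoulder_r": (-0.19, 1.0, 0.05 * min(t / 30, 1.0)),
            }, n_frames=60)
        out = trunk_compensation(seq, Segment(0, 59), "left")
        assert out["trunk_compensation"] == pytest.approx(0.05, abs=1e-9)
        assert out["shoulder_disp_z"] == pytest.approx(0.05, abs=1e-9)
        assert out["shoulder_disp_x"] == pytest.approx(0.0, abs=1e-9)


class TestHandGraspCoordination:
    def _hand(self, pitch):
        n = len(pitch)
        ch = np.zeros((n, len(HAND_CHANNELS)))
        ch[:, HAND_CHANNELS.index("wrist_pitch")] = pitch
        return HandSequence(np.arange(n) / 100.0, ch)

    def test_constant_pitch(self):
        out = hand_features(self._hand(np.full(30, 20.0)))
        assert out["wrist_pitch_max"] == 20.0
        assert out["wrist_pitch_min"] == 20.0
        assert out["wrist_pitch_rom"] == 0.0

    def test_pitch_ramp(self):
        out = hand_features(self._hand(np.linspace(-10, 25, 30)))
        assert out["wrist_pitch_max"] == pytest.approx(25.0)
        assert out["wrist_pitch_min"] == pytest.approx(-10.0)

    def test_item_feature_selection(self):
        out = wrist_hand_features(self._hand(np.zeros(30)), 19)
        assert set(out) == {"wrist_pitch_max", "wrist_pitch_min"}
        with pytest.raises(ValidationError):
            wrist_hand_features(self._hand(np.zeros(30)), 26)

    def test_finger_extension_range(self):
        n = 40
        ch = np.zeros((n, len(HAND_CHANNELS)))
        eta = np.concatenate([np.linspace(5, 95, 20),
                              np.linspace(95, 15, 20)])
        for i in range(1, 5):
            ch[:, HAND_CHANNELS.index(f"finger{i}")] = eta
        seq = HandSequence(np.arange(n) / 100.0, ch)
        out = hand_features(seq)
        assert out["finger1_flexion_max"] == pytest.approx(95.0)
        assert out["finger1_extension_range"] == pytest.approx(80.0)

    def test_grasp_peaks(self):
        rec = GraspRecording(np.arange(3) / 10.0, np.array([0.0, 0.3, 0.1]),
                            np.array([0.0, 2.5, 1.0]))
        out = grasp_features(rec)
        assert out["force_max"] == 2.5
        assert out["voltage_max"] == pytest.approx(0.3)

    def test_all_zero_force_is_valid(self):
        rec = GraspRecording(np.arange(5) / 10.0, np.zeros(5), np.zeros(5))
        assert grasp_features(rec)["force_max"] == 0.0

    def test_wrist_reaching_nose_has_zero_distance(self):
        def fn(t):
            frac = min(t / 40, 1.0)
            nose = np.array([0.0, 1.12, 0.09])
            start = np.array([0.3, 0.6, 0.3])
            return {"nose": tuple(nose),
                    "wrist_l": tuple(start + frac * (nose - start))}
        seq = make_skeleton(fn, n_frames=60)
        out = coordination_features(seq, Segment(0, 59), "left")
        assert out["nose_distance_min"] == pytest.approx(0.0, abs=1e-9)

    def test_segment_duration_at_30fps(self):
        def fn(t):
            return {"wrist_l": (0.3 - 0.005 * t, 0.6, 0.3)}
        seq = make_skeleton(fn, n_frames=80, fps=30.0)
        out = coordination_features(seq, Segment(0, 59), "left")
        assert out["movement_time"] == pytest.approx(2.0, abs=1e-9)


class TestShoulderElbowVector:
    @pytest.fixture()
    def moving_sequence(self):
        def fn(t):
            frac = min(t / 50, 1.0)
            sh = np.array([0.19, 1.0, 0.0])
            elbow = sh + 0.29 * np.array(
                [np.sin(0.2 + 1.2 * frac), -np.cos(0.2 + 1.2 * frac), 0.05])
            wrist = elbow + 0.26 * np.array(
                [np.sin(0.5 + frac), -np.cos(0.5 + frac), 0.1])
            return {"neck": (0, 1.05, 0), "mid_hip": (0, 0.55, 0),
                    "shoulder_l": tuple(sh), "shoulder_r": (-0.19, 1.0, 0.0),
                    "elbow_l": tuple(elbow), "wrist_l": tuple(wrist)}
        return make_skeleton(fn, n_frames=70)

    def test_exactly_36_named_entries(self, moving_sequence):
        vec = shoulder_elbow_vector(moving_sequence, Segment(5, 65), "left")
        assert len(vec) == 36
        assert set(vec) == set(SHOULDER_ELBOW_FEATURES)

    def test_entries_match_component_operations(self, moving_sequence):
        from fmascore.features import angular_features

        seg = Segment(5, 65)
        vec = shoulder_elbow_vector(moving_sequence, seg, "left")
        endpoint = endpoint_features(moving_sequence, seg, "wrist_l")
        for k, v in endpoint.items():
            assert vec[k] == v
        angles = joint_angles(moving_sequence, "left")
        elbow_stats = angular_features(angles["elbow_flexion"], seg, 30.0)
        for stat, v in elbow_stats.items():
            assert vec[f"elbow_flexion_{stat}"] == v

    def test_deterministic(self, moving_sequence):
        seg = Segment(5, 65)
        a = shoulder_elbow_vector(moving_sequence, seg, "left")
        b = shoulder_elbow_vector(moving_sequence, seg, "left")
        assert a == b

    def test_rom_is_max_minus_min_for_every_dof(self, moving_sequence):
        vec = shoulder_elbow_vector(moving_sequence, Segment(5, 65), "left")
        from fmascore.features import ANGLE_DOFS
        for dof in ANGLE_DOFS:
            assert vec[f"{dof}_rom"] == pytest.approx(
                vec[f"{dof}_angle_max"] - vec[f"{dof}_angle_min"], abs=1e-9)
            assert vec[f"{dof}_rom"] >= 0
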