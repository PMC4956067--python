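"""Dual-sensor calibration and per-joint fusion."""

import numpy as np
import pytest

from skillmatch.errors import (
    CalibrationRejectedError,
    MissingLandmarkError,
    NoOverlapError,
    ValidationError,
)
from skillmatch.fusion import Calibration, calibrate, fuse_streams, transform_frame
from skillmatch.skeleton import (
    Frame,
    FusionSource,
    JointId,
    N_JOINTS,
    SkeletonStream,
    TrackingState,
)
from skillmatch.synthetic import simulate_tpose


def _frame(positions, states=None, t=0.0):
    return Frame(
        t,
        np.asarray(positions, np.float32),
        np.full(N_JOINTS, 2, np.uint8) if states is None else np.asarray(states, np.uint8),
        np.zeros((N_JOINTS, 3), np.float32),
    )


class TestCalibrate:
    def test_identity_pair(self):
        f1, f2 = simulate_tpose(yaw_deg=0.0)
        calib = calibrate(f1, f2)
        assert calib.valid
        assert calib.yaw_deg == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(calib.translation, 0.0, atol=1e-6)

    @pytest.mark.parametrize("yaw", [-80.0, -45.0, -10.0, 15.0, 60.0, 80.0])
    def test_recovers_planted_yaw_noise_free(self, yaw):
        f1, f2 = simulate_tpose(yaw_deg=yaw, translation=(0.6, 0.0, -0.4))
        calib = calibrate(f1, f2)
        assert calib.yaw_deg == pytest.approx(yaw, abs=1e-6)
        assert calib.valid

    def test_recovers_yaw_under_centimetre_noise(self):
        errs = []
        for seed in range(10):
            f1, f2 = simulate_tpose(yaw_deg=40.0, translation=(0.5, 0, 0.2),
                                    noise_sd=0.01, seed=seed)
            errs.append(abs(calibrate(f1, f2, strict=False).yaw_deg - 40.0))
        assert max(errs) < 2.0

    def test_rejects_wrist_span_difference(self):
        f1, f2 = simulate_tpose(yaw_deg=0.0)
        pos2 = f2.positions.copy()
        pos2[int(JointId.WRIST_RIGHT), 0] -= 0.12  # shorten camera 2's span
        f2bad = _frame(pos2)
        with pytest.raises(CalibrationRejectedError, match="cm"):
            calibrate(f1, f2bad)
        calib = calibrate(f1, f2bad, strict=False)
        assert not calib.valid
        assert calib.wrist_distance_diff_m >= 0.10

    def test_untracked_wrist_is_an_error(self):
        f1, f2 = simulate_tpose()
        states = f1.states.copy()
        states[int(JointId.WRIST_LEFT)] = int(TrackingState.INFERRED)
        with pytest.raises(MissingLandmarkError):
            calibrate(_frame(f1.positions, states), f2)

    def test_json_round_trip(self, tmp_path):
        f1, f2 = simulate_tpose(yaw_deg=33.0, translation=(0.1, 0.0, 0.2))
        calib = calibrate(f1, f2)
        path = tmp_path / "calib.json"
        calib.to_json(path)
        back = Calibration.from_json(path)
        assert back.yaw_deg == pytest.approx(calib.yaw_deg)
        assert np.allclose(back.translation, calib.translation)
        assert back.valid == calib.valid


class TestTransform:
    def test_identity_calibration_is_noop(self):
        f1, _ = simulate_tpose()
        calib = Calibration(0.0, np.zeros(3), 0.0)
        out = transform_frame(f1, calib)
        assert np.allclose(out.positions, f1.positions)

    def test_hand_computed_rotation(self):
        # +90 deg yaw about Y maps X-forward onto -Z in the X-right/Y-up/
        # Z-away convention
        calib = Calibration(90.0, np.zeros(3), 0.0)
        out = calib.apply(np.array([1.0, 0.0, 0.0]))
        assert np.allclose(out, [0.0, 0.0, -1.0], atol=1e-9)

    def test_inverse_recovers_original(self):
        rng = np.random.default_rng(5)
        calib = Calibration(37.0, np.array([0.4, -0.1, 0.8]), 0.0)
        pts = rng.normal(size=(50, 3))
        assert np.allclose(calib.apply_inverse(calib.apply(pts)), pts, atol=1e-9)

    def test_invalid_calibration_refused(self):
        f1, _ = simulate_tpose()
        calib = Calibration(0.0, np.zeros(3), 0.2)
        with pytest.raises(ValidationError):
            transform_frame(f1, calib)


def _stream_with_states(pos_value, states_row, n=5):
    t = np.arange(n) / 30.0
    pos = np.full((n, N_JOINTS, 3), 0.0, np.float32)
    pos[:] = pos_value
    states = np.tile(np.asarray(states_row, np.uint8), (n, 1))
    return SkeletonStream(t, pos, states,
                          np.zeros((n, N_JOINTS, 3), np.float32), nominal_rate=30.0)


class TestFusion:
    identity = Calibration(0.0, np.zeros(3), 0.0)

    def test_average_branch(self):
        s1 = _stream_with_states([0.10, 1.00, 2.00], [2] * N_JOINTS)
        s2 = _stream_with_states([0.20, 1.00, 2.00], [2] * N_JOINTS)
        fused = fuse_streams(s1, s2, self.identity)
        assert np.allclose(fused.positions[0, 0], [0.15, 1.00, 2.00])
        assert (fused.provenance == int(FusionSource.AVERAGED)).all()

    def test_single_camera_branches(self):
        st1 = [2] * N_JOINTS
        st2 = [2] * N_JOINTS
        st1[3] = 0  # camera 1 lost the head -> camera 2's value
        st2[5] = 0  # camera 2 lost left elbow -> camera 1's value
        s1 = _stream_with_states([0.3, 0.9, 2.1], st1)
        s2 = _stream_with_states([0.5, 1.1, 2.3], st2)
        fused = fuse_streams(s1, s2, self.identity)
        assert np.allclose(fused.positions[0, 5], [0.3, 0.9, 2.1])
        assert fused.provenance[0, 5] == int(FusionSource.CAM1_ONLY)
        assert np.allclose(fused.positions[0, 3], [0.5, 1.1, 2.3])
        assert fused.provenance[0, 3] == int(FusionSource.CAM2_ONLY)

    def test_fallback_branch_keeps_camera1(self):
        st = [2] * N_JOINTS
        st[7] = 0
        s1 = _stream_with_states([0.3, 0.9, 2.1], st)
        s2 = _stream_with_states([0.9, 0.9, 2.1], st)
        fused = fuse_streams(s1, s2, self.identity)
        assert np.allclose(fused.positions[0, 7], [0.3, 0.9, 2.1])
        assert fused.provenance[0, 7] == int(FusionSource.FALLBACK_CAM1)
        assert fused.states[0, 7] == int(TrackingState.NOT_TRACKED)

    def test_tracked_beats_inferred(self):
        st1 = [2] * N_JOINTS
        st2 = [2] * N_JOINTS
        st2[4] = 1  # camera 2 merely infers the left shoulder
        s1 = _stream_with_states([0.1, 1.0, 2.0], st1)
        s2 = _stream_with_states([0.9, 1.0, 2.0], st2)
        fused = fuse_streams(s1, s2, self.identity)
        assert np.allclose(fused.positions[0, 4], [0.1, 1.0, 2.0])
        assert fused.provenance[0, 4] == int(FusionSource.CAM1_ONLY)

    def test_self_fusion_returns_original_positions(self):
        rng = np.random.default_rng(2)
        n = 20
        t = np.arange(n) / 30.0
        pos = rng.normal(0, 1, (n, N_JOINTS, 3)).astype(np.float32)
        states = np.full((n, N_JOINTS), 2, np.uint8)
        s = SkeletonStream(t, pos, states, np.zeros((n, N_JOINTS, 3), np.float32))
        fused = fuse_streams(s, s.copy(), self.identity)
        assert np.allclose(fused.positions, s.positions)
        assert (fused.provenance == int(FusionSource.AVERAGED)).all()

    def test_fused_lies_between_inputs(self):
        rng = np.random.default_rng(3)
        n = 10
        t = np.arange(n) / 30.0
        mk = lambda: SkeletonStream(
            t, rng.normal(0, 1, (n, N_JOINTS, 3)).astype(np.float32),
            np.full((n, N_JOINTS), 2, np.uint8), np.zeros((n, N_JOINTS, 3), np.float32))
        s1, s2 = mk(), mk()
        fused = fuse_streams(s1, s2, self.identity)
        lo = np.minimum(s1.positions, s2.positions) - 1e-6
        hi = np.maximum(s1.positions, s2.positions) + 1e-6
        assert ((fused.positions >= lo) & (fused.positions <= hi)).all()

    def test_no_time_overlap_is_an_error(self):
        s1 = _stream_with_states([0.1, 1.0, 2.0], [2] * N_JOINTS)
        n = 5
        t = 100.0 + np.arange(n) / 30.0
        s2 = SkeletonStream(t, np.zeros((n, N_JOINTS, 3), np.float32),
                            np.full((n, N_JOINTS), 2, np.uint8),
                            np.zeros((n, N_JOINTS, 3), np.float32))
        with pytest.raises(NoOverlapError):
            fuse_streams(s1, s2, self.identity)
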