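"""Calibrations, subpixel registration, trajectory integration and head
targeting."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, map_coordinates

from wormetho import posture as po
from wormetho import register as rg


def make_texture(seed=3, sigma=1.5, n=512):
    rng = np.random.default_rng(seed)
    tex = gaussian_filter(rng.standard_normal((n, n)), sigma, mode="wrap")
    return tex / tex.std()


def sample_window(tex, shift_xy, shape=(128, 128)):
    """Camera window at stage position `shift_xy` (x=cols, y=rows) px."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    coords = [(rr + shift_xy[1]).ravel(), (cc + shift_xy[0]).ravel()]
    return map_coordinates(tex, coords, order=3,
                           mode="grid-wrap").reshape(H, W)


class TestCalibrateStage:
    def test_scale_with_axis_inversion_recovered(self):
        # stationary object appears at px when the stage sits at mm:
        # a -10 px move of the object for +0.1 mm stage is a -0.01 mm/px
        # x-gain seen from the object side; the fitted pixel->mm map must
        # reproduce the hand-solved 2x2 system
        px = np.array([[0, 0], [-10, 0], [-10, 20], [5, -8]], dtype=float)
        A_true = np.array([[-0.01, 0.0], [0.0, 0.005]])
        mm = px @ A_true.T + np.array([1.0, 2.0])
        cal = rg.calibrate_stage(px, mm)
        assert np.allclose(cal.matrix, A_true, atol=1e-12)
        assert cal.residual == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_zero_residual(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(-50, 50, (8, 2))
        A = np.array([[0.011, 0.001], [-0.002, 0.0095]])
        mm = px @ A.T + [0.3, -0.2]
        cal = rg.calibrate_stage(px, mm)
        assert cal.residual < 1e-12

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            rg.calibrate_stage(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_collinear_rejected(self):
        px = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            rg.calibrate_stage(px, px * 0.01)

    def test_json_round_trip(self, tmp_path):
        cal = rg.CalibrationTransform(np.array([[0.01, 0], [0, 0.01]]),
                                      np.array([1.0, 2.0]), 0.001)
        cal.to_json(tmp_path / "c.json")
        back = rg.CalibrationTransform.from_json(tmp_path / "c.json")
        assert np.allclose(back.matrix, cal.matrix)
        assert np.allclose(back.offset, cal.offset)


class TestCalibrateGalvo:
    def test_identity_mapping(self):
        v = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        fwd, inv = rg.calibrate_galvo(v, v)
        assert np.allclose(fwd.apply([0.3, 0.7]), [0.3, 0.7])

    def test_rotation_and_gain_recovered(self):
        a = np.deg2rad(5)
        A = (1 / 0.02) * np.array([[np.cos(a), -np.sin(a)],
                                   [np.sin(a), np.cos(a)]])  # 0.02 V/px
        rng = np.random.default_rng(1)
        volts = rng.uniform(-1, 1, (10, 2))
        pxs = volts @ A.T
        fwd, inv = rg.calibrate_galvo(volts, pxs)
        assert np.abs(fwd.matrix - A).max() < 1e-6
        assert np.allclose(inv.apply(pxs[0]), volts[0], atol=1e-9)

    def test_noisy_clicks_residual_near_sigma(self):
        rng = np.random.default_rng(2)
        A = np.array([[50.0, 0], [0, 50.0]])
        resids = []
        for _ in range(30):
            volts = rng.uniform(-1, 1, (12, 2))
            pxs = volts @ A.T + rng.standard_normal((12, 2))  # sigma = 1 px
            fwd, _ = rg.calibrate_galvo(volts, pxs)
            resids.append(fwd.residual)
        # Monte-Carlo: the residual is a 2-D distance rms, so it
        # concentrates at sigma * sqrt(2 * (1 - 3/12)) ~ 1.22 sigma
        # (each axis fit absorbs 3 of 12 dof)
        expected = np.sqrt(2 * (1 - 3 / 12))
        assert np.mean(resids) == pytest.approx(expected, rel=0.15)


class TestEstimateShift:
    def test_identical_frames_zero(self):
        tex = make_texture()
        f = sample_window(tex, (0, 0))
        est = rg.estimate_shift(f, f)
        assert est.dx == 0.0 and est.dy == 0.0

    @pytest.mark.parametrize("true", [(3.25, -1.50), (0.10, 0.00),
                                      (9.70, 9.90), (-10.0, 4.33)])
    def test_subpixel_accuracy_within_005(self, true):
        tex = make_texture()
        a = sample_window(tex, (0, 0))
        b = sample_window(tex, true)
        est = rg.estimate_shift(a, b)
        assert abs(est.dx - true[0]) <= 0.05
        assert abs(est.dy - true[1]) <= 0.05

    def test_oracle_agreement_20x_brute_force(self):
        # oracle: brute-force cross-correlation on a 20x upsampled grid
        tex = make_texture(seed=8)
        true = (2.35, -0.85)
        a = sample_window(tex, (0, 0), (96, 96))
        b = sample_window(tex, true, (96, 96))
        best, best_err = None, np.inf
        for dx20 in range(int(true[0] * 20) - 10, int(true[0] * 20) + 11):
            for dy20 in range(int(true[1] * 20) - 10, int(true[1] * 20) + 11):
                shifted = sample_window(tex, (dx20 / 20, dy20 / 20), (96, 96))
                err = ((shifted - b) ** 2).mean()
                if err < best_err:
                    best, best_err = (dx20 / 20, dy20 / 20), err
        est = rg.estimate_shift(a, b)
        assert abs(est.dx - best[0]) <= 0.05
        assert abs(est.dy - best[1]) <= 0.05

    def test_textureless_region_low_confidence(self):
        f = np.full((96, 96), 0.5)
        est = rg.estimate_shift(f, f)
        assert not est.confident
        assert (est.dx, est.dy) == (0.0, 0.0)

    def test_edge_region_mask_excludes_dilated_worm(self):
        worm = np.zeros((100, 100), bool)
        worm[10:14, 40:60] = True  # worm crossing the top border band
        region = rg.edge_region_mask((100, 100), 0.15, worm,
                                     worm_dilate_px=3)
        assert not region[10:14, 40:60].any()
        assert region[:5, :5].all()  # corners remain
        assert not region[40:60, 40:60].any()  # interior never included

    def test_strip_estimator_ignores_independent_mover(self):
        # a central object moving against the stage must not bias the
        # strip-based stage estimate
        tex = make_texture(seed=11)
        a = sample_window(tex, (0.0, 0.0), (160, 160))
        b = sample_window(tex, (2.4, -1.2), (160, 160))
        worm = np.zeros((160, 160), bool)
        worm[70:90, 70:90] = True
        a2, b2 = a.copy(), b.copy()
        a2[70:90, 70:90] = 5.0
        b2[75:95, 60:80] = 5.0  # moved the other way
        est = rg.estimate_strip_shift(a2, b2, worm)
        assert abs(est.dx - 2.4) <= 0.05
        assert abs(est.dy + 1.2) <= 0.05


class TestIntegrateStageMotion:
    def test_constant_drift_noiseless_exactly_linear(self):
        n = 200
        shifts = {1: np.full((n, 2), 0.5), 2: np.full((n, 2), 1.0),
                  3: np.full((n, 2), 1.5)}
        for lag in shifts:
            shifts[lag][:lag] = np.nan
        traj = rg.integrate_stage_motion(shifts, (1.0, -1.0),
                                         pixel_size_mm=0.01)
        d = np.diff(traj.position_mm, axis=0)
        assert np.allclose(d, 0.5 * 0.01)
        assert np.allclose(traj.position_mm[0], [1.0, -1.0] )

    def test_lag_averaging_beats_lag1_variance(self):
        # Monte-Carlo: white error on every pairwise estimate
        rng = np.random.default_rng(0)
        n, sigma, reps = 300, 0.05, 40
        var_avg, var_lag1 = [], []
        for _ in range(reps):
            true_inc = np.zeros((n, 2))
            shifts = {}
            for lag in (1, 2, 3):
                s = np.full((n, 2), np.nan)
                for i in range(lag, n):
                    s[i] = true_inc[i - lag + 1:i + 1].sum(axis=0) \
                        + sigma * rng.standard_normal(2)
                shifts[lag] = s
            t_avg = rg.integrate_stage_motion(shifts, (0, 0),
                                              pixel_size_mm=1.0)
            t_l1 = rg.integrate_stage_motion({1: shifts[1]}, (0, 0),
                                             pixel_size_mm=1.0)
            var_avg.append((t_avg.position_mm[-1] ** 2).sum())
            var_lag1.append((t_l1.position_mm[-1] ** 2).sum())
        assert np.mean(var_avg) < np.mean(var_lag1)

    def test_zero_shifts_constant_at_start(self):
        n = 50
        shifts = {1: np.zeros((n, 2))}
        shifts[1][:1] = np.nan
        traj = rg.integrate_stage_motion(shifts, (0.4, 0.2),
                                         pixel_size_mm=0.01)
        assert np.allclose(traj.position_mm, [0.4, 0.2])

    def test_missing_frame_interpolated_and_flagged(self):
        n = 60
        shifts = {1: np.full((n, 2), 0.5)}
        shifts[1][0] = np.nan
        shifts[1][30] = np.nan
        traj = rg.integrate_stage_motion(shifts, (0, 0), pixel_size_mm=1.0)
        assert traj.source[30] == "interpolated"
        assert np.allclose(np.diff(traj.position_mm, axis=0), 0.5)


class TestToWorld:
    def test_identity_scaled_cal(self):
        cal = rg.CalibrationTransform(0.01 * np.eye(2), np.zeros(2))
        w = rg.to_world(np.array([10.0, 20.0]), np.zeros(2), cal)
        assert np.allclose(w, [0.1, 0.2])

    def test_translation_equivariance(self):
        cal = rg.CalibrationTransform(0.01 * np.eye(2), np.zeros(2))
        p = np.array([7.0, 3.0])
        w0 = rg.to_world(p, np.array([0.0, 0.0]), cal)
        w1 = rg.to_world(p, np.array([1.0, 0.0]), cal)
        assert np.allclose(w1 - w0, [1.0, 0.0])

    def test_round_trip_identity(self):
        cal = rg.CalibrationTransform(np.array([[0.011, 0.001],
                                                [-0.001, 0.012]]),
                                      np.array([0.5, -0.5]))
        p = np.array([3.3, -7.7])
        stage = np.array([1.2, 3.4])
        w = rg.to_world(p, stage, cal)
        back = rg.from_world(w, stage, cal)
        assert np.abs(back - p).max() < 1e-9


class TestTargetHead:
    def _straight_skeleton(self, length_px=80.0):
        pts = np.column_stack([np.linspace(0, length_px, 49), np.zeros(49)])
        return po.Skeleton(pts, oriented=True)

    def test_anterior_fifth_midpoint(self):
        sk = self._straight_skeleton(80.0)  # 1 mm at 0.0125 mm/px
        target, _ = rg.target_head(sk, fraction=0.2)
        assert np.allclose(target, [8.0, 0.0], atol=0.1)  # 0.1 mm from tip

    def test_lag_error_speed_over_frame_rate(self):
        sk = self._straight_skeleton()
        _, lag = rg.target_head(sk, 0.2, speed_mm_s=0.2, frame_rate_hz=20.0)
        assert lag == pytest.approx(0.01)

    def test_fraction_one_targets_body_midpoint(self):
        sk = self._straight_skeleton(80.0)
        target, _ = rg.target_head(sk, fraction=1.0)
        assert np.allclose(target, [40.0, 0.0], atol=0.1)

    def test_complex_frame_rejected(self):
        sk = po.Skeleton(np.full((49, 2), np.nan), complex=True)
        with pytest.raises(ValueError, match="complex"):
            rg.target_head(sk)

    def test_closed_loop_targeting_error_shrinks_with_frame_rate(self):
        # monotonicity: the predicted lag error is speed / frame rate
        sk = self._straight_skeleton()
        errs = [rg.target_head(sk, 0.2, speed_mm_s=0.2,
                               frame_rate_hz=f)[1] for f in (10, 15, 20)]
        assert errs[0] > errs[1] > errs[2]
        errs_speed = [rg.target_head(sk, 0.2, speed_mm_s=s,
                                     frame_rate_hz=20.0)[1]
                      for s in (0.1, 0.2, 0.4)]
        assert errs_speed[0] < errs_speed[1] < errs_speed[2]
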