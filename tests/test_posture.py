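"""Midline accuracy, eigenworm algebra, posture-space repair and
head-tail orientation."""

import numpy as np
import pytest

from wormetho import posture as po
from wormetho import segment as sg
from wormetho import synthworm as sw
from wormetho.core import StimulusEvent

from conftest import truth_skeletons_px


def _flip_rmse(a, b):
    e1 = np.sqrt(((a - b) ** 2).sum(axis=1).mean())
    e2 = np.sqrt(((a[::-1] - b) ** 2).sum(axis=1).mean())
    return min(e1, e2)


@pytest.fixture(scope="module")
def rod_mask():
    m = np.zeros((40, 120), bool)
    m[18:23, 10:110] = True  # 100 x 5 straight rod
    return sg.BinaryMask(m)


class TestMidlineSimple:
    def test_straight_rod_length_and_straightness(self, rod_mask):
        # square-ended rod: no taper, so no tip-clip compensation
        sk = po.midline_simple(rod_mask, tip_extend_px=0.0)
        assert sk.arc_length == pytest.approx(100, abs=2)
        # oracle: the rod axis y = 20
        resid = sk.points[:, 1] - 20.0
        assert np.sqrt((resid**2).mean()) < 0.5

    @pytest.mark.parametrize("amplitude", [0.4, 0.7, 1.0])
    def test_sinusoid_worm_midline_rmse_below_1px(self, amplitude):
        sched = sw.LocomotionSchedule(
            [sw.ScheduleSegment("forward", 3.0, 0.15, 0.5, amplitude)],
            seed=2, heading_noise=0.0)
        truth = sw.generate_track(sched)
        rec = sw.render_frames(truth, sw.Optics(noise_frac=0.02, seed=7))
        masks, _ = sg.segment_stack(rec.stack, sg.SegmentationConfig())
        tp = truth_skeletons_px(truth, rec)
        errs = [
            _flip_rmse(po.midline_simple(m).points, tp[i])
            for i, m in enumerate(masks)
        ]
        assert np.mean(errs) < 1.0
        # endpoints land within 2 px of the true tips
        sk = po.midline_simple(masks[10]).points
        tips_err = min(
            max(np.linalg.norm(sk[0] - tp[10][0]),
                np.linalg.norm(sk[-1] - tp[10][-1])),
            max(np.linalg.norm(sk[0] - tp[10][-1]),
                np.linalg.norm(sk[-1] - tp[10][0])))
        assert tips_err < 2.0

    def test_looped_mask_raises_complex_flag(self, escape_recording):
        truth = escape_recording.truth
        masks, _ = sg.segment_stack(escape_recording.stack,
                                    sg.SegmentationConfig())
        ti = np.flatnonzero(truth.states == "turn")
        mid = int(ti[len(ti) // 2])
        sk = po.midline_simple(masks[mid])
        assert sk.complex
        assert np.isnan(sk.points).all()

    def test_spacing_uniform_within_5pct(self, rod_mask):
        sk = po.midline_simple(rod_mask)
        gaps = np.linalg.norm(np.diff(sk.points, axis=0), axis=1)
        assert gaps.max() / gaps.min() < 1.05


class TestFlagComplexFrames:
    def test_all_forward_recording_has_no_flags(self, forward_truth):
        rec = sw.render_frames(forward_truth,
                               sw.Optics(noise_frac=0.02, seed=3))
        masks, _ = sg.segment_stack(rec.stack, sg.SegmentationConfig())
        sks = po.midline_series(masks)
        assert len(po.flag_complex_frames(sks)) <= 1  # lone mask glitches only

    def test_turn_frames_flagged(self, escape_recording):
        truth = escape_recording.truth
        masks, _ = sg.segment_stack(escape_recording.stack,
                                    sg.SegmentationConfig())
        sks = po.midline_series(masks)
        flags = po.flag_complex_frames(sks)
        ti = np.flatnonzero(truth.states == "turn")
        # the deep-coil portion of the turn must be in the work list
        mid = ti[len(ti) // 3: 2 * len(ti) // 3]
        assert np.isin(mid, flags).all()

    def test_single_corrupted_frame_flagged(self, forward_truth):
        rec = sw.render_frames(forward_truth,
                               sw.Optics(noise_frac=0.02, seed=3))
        masks, _ = sg.segment_stack(rec.stack, sg.SegmentationConfig())
        sks = po.midline_series(masks)
        bad = po.Skeleton(sks[40].points * 1.6, frame=40)  # length outlier
        sks[40] = bad
        assert 40 in po.flag_complex_frames(sks)


@pytest.fixture(scope="module")
def truth_skeleton_series(forward_truth):
    px = forward_truth.pixel_size_mm
    return [
        po.Skeleton(p / px, frame=i, oriented=True)
        for i, p in enumerate(forward_truth.skeletons_mm)
    ]


@pytest.fixture(scope="module")
def basis(truth_skeleton_series):
    return po.build_eigenbasis(truth_skeleton_series)


class TestEigenbasis:
    def test_first_two_modes_dominate_sinusoidal_crawl(self, basis):
        assert basis.explained_variance[:2].sum() >= 0.90

    def test_modes_orthonormal(self, basis):
        gram = basis.modes @ basis.modes.T
        assert np.abs(gram - np.eye(basis.k)).max() < 1e-10

    def test_matches_direct_eigendecomposition(self, truth_skeleton_series,
                                               basis):
        # oracle: eigendecomposition of the angle-profile covariance
        X = np.array([po._centered_angles(s.points)
                      for s in truth_skeleton_series])
        C = np.cov((X - X.mean(0)).T)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        frac = evals[:2].sum() / evals.sum()
        assert basis.explained_variance[:2].sum() == pytest.approx(frac,
                                                                   rel=1e-6)

    def test_reconstruction_residual_below_10pct(self, truth_skeleton_series,
                                                 basis):
        sk = truth_skeleton_series[37]
        a = po.project_modes(sk, basis)
        prof = po._centered_angles(sk.points) - basis.mean_profile
        recon = a @ basis.modes
        assert np.sqrt(((prof - recon) ** 2).mean()) < 0.1 * np.sqrt(
            (prof**2).mean())

    def test_insufficient_sample_rejected(self, truth_skeleton_series):
        with pytest.raises(ValueError, match="100"):
            po.build_eigenbasis(truth_skeleton_series[:10])

    def test_csv_round_trip(self, basis, tmp_path):
        basis.to_csv(tmp_path / "b.csv")
        back = po.EigenwormBasis.from_csv(tmp_path / "b.csv")
        assert np.allclose(back.modes, basis.modes)
        assert np.allclose(back.mean_profile, basis.mean_profile)


class TestProjectModes:
    def test_mean_profile_projects_to_zero(self, basis):
        ang = basis.mean_profile.copy()
        pts = np.vstack([[0, 0], np.cumsum(
            np.column_stack([np.cos(ang), np.sin(ang)]), axis=0)])
        sk = po.Skeleton(pts, oriented=True)
        a = po.project_modes(sk, basis)
        assert np.abs(a).max() < 1e-8

    def test_orthonormal_projection_recovers_coefficient(self, basis):
        ang = basis.mean_profile + 2.0 * basis.modes[0]
        ang = ang - ang.mean()  # projection removes rotation anyway
        pts = np.vstack([[0, 0], np.cumsum(
            np.column_stack([np.cos(ang), np.sin(ang)]), axis=0)])
        sk = po.Skeleton(pts, oriented=True)
        a = po.project_modes(sk, basis)
        assert a[0] == pytest.approx(2.0, abs=1e-6)
        assert np.abs(a[1:]).max() < 1e-6

    def test_flipped_skeleton_projects_differently(
            self, truth_skeleton_series, basis):
        sk = truth_skeleton_series[11]
        a = po.project_modes(sk, basis)
        a_flip = po.project_modes(sk.flipped(), basis)
        # oracle: explicit reversal computation on the angle profile
        ang = po.tangent_angles(sk.points[::-1])
        prof = (ang - ang.mean()) - basis.mean_profile
        assert np.allclose(a_flip, basis.modes @ prof)
        assert not np.allclose(a_flip, a)

    def test_unoriented_skeleton_rejected(self, truth_skeleton_series, basis):
        sk = po.Skeleton(truth_skeleton_series[0].points, oriented=False)
        with pytest.raises(ValueError, match="orient"):
            po.project_modes(sk, basis)


class TestInterpolateComplex:
    def test_no_complex_frames_near_identity(self, truth_skeleton_series,
                                             basis):
        modes, _ = po.project_series(truth_skeleton_series, basis)
        out, missing, _ = po.interpolate_complex(
            modes, np.zeros(len(modes), bool), 20.0)
        assert not missing.any()
        assert np.abs(out - modes).max() < 1e-3

    def test_gap_on_mode_circle_interpolated(self):
        # (a1, a2) on an analytic circle; 5-frame gap
        fps, f = 20.0, 0.5
        t = np.arange(200) / fps
        modes = np.column_stack([
            3 * np.cos(2 * np.pi * f * t), -3 * np.sin(2 * np.pi * f * t),
            np.zeros_like(t), np.zeros_like(t)])
        flags = np.zeros(200, bool)
        flags[90:95] = True
        out, missing, _ = po.interpolate_complex(modes, flags, fps)
        assert not missing.any()
        phi_true = np.arctan2(-modes[90:95, 1], modes[90:95, 0]) / (2 * np.pi)
        phi_est = np.arctan2(-out[90:95, 1], out[90:95, 0]) / (2 * np.pi)
        err = np.abs((phi_est - phi_true + 0.5) % 1.0 - 0.5)
        assert err.max() < 0.05

    def test_gap_at_start_marked_missing(self, truth_skeleton_series, basis):
        modes, _ = po.project_series(truth_skeleton_series, basis)
        flags = np.zeros(len(modes), bool)
        flags[:8] = True
        out, missing, _ = po.interpolate_complex(modes, flags, 20.0)
        assert missing[:8].all()
        assert np.isnan(out[:8]).all()

    def test_long_gap_marked_missing_not_fabricated(
            self, truth_skeleton_series, basis):
        modes, _ = po.project_series(truth_skeleton_series, basis)
        flags = np.zeros(len(modes), bool)
        flags[50:100] = True  # 2.5 s at 20 Hz > 2 s default cap
        out, missing, _ = po.interpolate_complex(modes, flags, 20.0)
        assert missing[50:100].all()

    def test_reconstructed_skeletons_flagged(self, truth_skeleton_series,
                                             basis):
        modes, _ = po.project_series(truth_skeleton_series, basis)
        flags = np.zeros(len(modes), bool)
        flags[60:64] = True
        _, _, recon = po.interpolate_complex(
            modes, flags, 20.0, basis, truth_skeleton_series)
        assert all(recon[i].reconstructed for i in range(60, 64))
        # repaired skeleton stays close to the truth it replaced
        rmse = _flip_rmse(recon[61].points, truth_skeleton_series[61].points)
        assert rmse < 2.0


class TestCorrectHeadTail:
    """Orientation on open (non-coiled) postures: a coil brings head and
    tail tips together, which is precisely why coiled frames go through
    the complex-frame machinery instead of endpoint tracking."""

    @staticmethod
    def _anchored(truth):
        px = truth.pixel_size_mm
        sks = [po.Skeleton(p / px, frame=i)
               for i, p in enumerate(truth.skeletons_mm)]
        ev = sw.make_stimulus_event(truth, truth.timestamps[100])
        anchor = StimulusEvent(ev.time_s, ev.frame,
                               tuple(np.asarray(ev.target_mm) / px))
        return sks, anchor

    def test_consistent_series_unchanged(self, forward_truth):
        sks, anchor = self._anchored(forward_truth)
        oriented, flips, _ = po.correct_head_tail(sks, [anchor])
        assert not flips.any()
        assert all(s.oriented for s in oriented)

    def test_injected_flips_fully_restored(self, forward_truth):
        rng = np.random.default_rng(0)
        sks, anchor = self._anchored(forward_truth)
        for i in rng.choice(len(sks), 40, replace=False):
            sks[i] = sks[i].flipped()
        oriented, flips, _ = po.correct_head_tail(sks, [anchor])
        heads = np.array([s.points[0] for s in oriented])
        true_heads = forward_truth.skeletons_mm[:, 0, :] / forward_truth.pixel_size_mm
        assert np.allclose(heads, true_heads)

    def test_equidistant_anchor_requests_annotation(self):
        pts = np.column_stack([np.linspace(0, 48, 49), np.zeros(49)])
        sks = [po.Skeleton(pts.copy(), frame=i) for i in range(5)]
        anchor = StimulusEvent(0.0, 2, (24.0, 10.0))  # exact midpoint
        with pytest.raises(ValueError, match="ambiguous"):
            po.correct_head_tail(sks, [anchor])

    def test_idempotent(self, forward_truth):
        sks, anchor = self._anchored(forward_truth)
        sks[5] = sks[5].flipped()
        once, _, _ = po.correct_head_tail(sks, [anchor])
        twice, flips2, _ = po.correct_head_tail(once, [anchor])
        assert not flips2.any()

    def test_no_anchor_demands_annotation(self, truth_skeleton_series):
        sks = [po.Skeleton(s.points.copy(), frame=i)
               for i, s in enumerate(truth_skeleton_series)]
        with pytest.raises(ValueError, match="anchor"):
            po.correct_head_tail(sks, [])


class TestPostureInvariants:
    def test_mode_trajectory_winds_at_undulation_frequency(
            self, forward_truth, truth_skeleton_series, basis):
        modes, _ = po.project_series(truth_skeleton_series, basis)
        ang = np.unwrap(np.arctan2(modes[:, 1], modes[:, 0]))
        rate = np.abs(ang[-1] - ang[0]) / (2 * np.pi) / (
            forward_truth.timestamps[-1] - forward_truth.timestamps[0])
        assert rate == pytest.approx(0.5, rel=0.02)

    def test_arc_length_conserved_on_non_complex_frames(
            self, escape_recording):
        masks, _ = sg.segment_stack(escape_recording.stack,
                                    sg.SegmentationConfig())
        sks = po.midline_series(masks)
        lengths = np.array([s.arc_length for s in sks if not s.complex])
        med = np.median(lengths)
        assert (np.abs(lengths - med) < 0.05 * med).mean() > 0.95
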