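"""Preprocessing chain: motion handling, background, detection."""

import numpy as np
import pytest

from mulm import phantom, preproc
from mulm.core import FrameStack, MotionEstimate


def speckle_stack(n_frames=6, shape=(60, 60), seed=0, frame_rate=50.0):
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    base = np.abs(ndimage.gaussian_filter(rng.normal(size=shape), 1.5)) + 0.1
    return FrameStack(
        frames=np.tile(base, (n_frames, 1, 1)),
        frame_rate=frame_rate,
        pixel_spacing=(11.6, 11.6),
    )


class TestRigidMotion:
    def test_zero_motion_gives_zero_displacement(self):
        stack = speckle_stack()
        motion = preproc.estimate_rigid_motion(stack)
        np.testing.assert_array_equal(motion.displacement_um, 0.0)
        assert not motion.excluded.any()

    def test_known_shift_recovered_within_half_upsampled_pixel(self):
        stack = speckle_stack(n_frames=3)
        truth = phantom.PhantomTruth(segments=[], bubble_tracks=[], n_frames=3, frame_rate=50.0)
        motion_um = np.array([[0.0, 0.0], [12.0, -8.0], [12.0, -8.0]])
        rendered = phantom.render_frames(
            truth, (696.0, 696.0), background_amplitude=0.5,
            motion_profile_um=motion_um, seed=4,
        )
        est = preproc.estimate_rigid_motion(rendered, upsample_factor=4)
        quantum = 11.6 / 4
        assert np.all(
            np.abs(est.displacement_um[1:] - motion_um[1:]) <= quantum / 2 + 1e-9
        )

    def test_displacement_quantum_matches_upsampling(self):
        # 4-fold interpolation on 11.6 µm pixels resolves 2.9 µm steps
        stack = speckle_stack(n_frames=3)
        truth = phantom.PhantomTruth(segments=[], bubble_tracks=[], n_frames=3, frame_rate=50.0)
        rendered = phantom.render_frames(
            truth, (696.0, 696.0), background_amplitude=0.5,
            motion_profile_um=np.array([[0, 0], [13.0, 0.0], [0.0, 0.0]]), seed=4,
        )
        est = preproc.estimate_rigid_motion(rendered, upsample_factor=4)
        steps = est.displacement_um / (11.6 / 4)
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-6)

    def test_blank_frame_flagged_excluded(self):
        stack = speckle_stack(n_frames=3)
        stack.frames[2] = 0.0
        motion = preproc.estimate_rigid_motion(stack)
        assert motion.excluded[2]
        assert np.isnan(motion.correlation[2])


class TestExcludeFrames:
    def _motion(self, mags, corrs):
        disp = np.zeros((len(mags), 2))
        disp[:, 0] = mags
        return MotionEstimate(
            displacement_um=disp,
            correlation=np.asarray(corrs, dtype=float),
            excluded=np.zeros(len(mags), dtype=bool),
        )

    def test_vacuous_limits_exclude_nothing(self):
        m = self._motion([0, 10, 100], [1.0, 0.5, 0.1])
        out = preproc.exclude_frames(m, displacement_limit_um=np.inf, correlation_floor=-1.0)
        assert not out.excluded.any()

    def test_spike_frames_excluded_exactly(self):
        mags = [0.0, 5, 80, 6, 80, 7, 80, 8, 80, 3, 80, 2]
        corrs = [1.0] * 12
        out = preproc.exclude_frames(self._motion(mags, corrs), 40.0, 0.8)
        assert list(np.flatnonzero(out.excluded)) == [2, 4, 6, 8, 10]
        retained = np.asarray(mags)[~out.excluded]
        assert retained.max() <= 40.0

    def test_low_correlation_excluded(self):
        out = preproc.exclude_frames(self._motion([0, 0, 0], [1.0, 0.5, 0.9]), 40.0, 0.8)
        assert list(np.flatnonzero(out.excluded)) == [1]

    def test_all_excluded_is_hard_error(self):
        with pytest.raises(RuntimeError, match="no usable frames"):
            preproc.exclude_frames(self._motion([100, 100], [1.0, 1.0]), 40.0, 0.8)


class TestCompensateMotion:
    def test_zero_displacement_is_identity(self):
        stack = speckle_stack()
        motion = MotionEstimate(
            displacement_um=np.zeros((6, 2)),
            correlation=np.ones(6),
            excluded=np.zeros(6, dtype=bool),
        )
        out = preproc.compensate_motion(stack, motion)
        np.testing.assert_array_equal(out.frames, stack.frames)

    def test_static_bubble_under_motion_recentres(self):
        # a bubble rendered with rigid motion returns to a fixed centroid
        n = 4
        tr = phantom.BubbleTrack(
            frames=np.arange(n), positions=np.tile([348.0, 348.0], (n, 1)), segment_index=0
        )
        truth = phantom.PhantomTruth(segments=[], bubble_tracks=[tr], n_frames=n, frame_rate=50.0)
        motion_um = np.array([[0, 0], [11.6, 0], [0, 23.2], [11.6, 11.6]], dtype=float)
        stack = phantom.render_frames(
            truth, (696.0, 696.0), background_amplitude=0.0, motion_profile_um=motion_um
        )
        est = MotionEstimate(
            displacement_um=motion_um, correlation=np.ones(n), excluded=np.zeros(n, bool)
        )
        comp = preproc.compensate_motion(stack, est)
        centroids = []
        rr, cc = np.mgrid[: stack.shape[0], : stack.shape[1]]
        for f in range(n):
            w = comp.frames[f] / comp.frames[f].sum()
            centroids.append([(rr * w).sum() * 11.6, (cc * w).sum() * 11.6])
        centroids = np.array(centroids)
        assert np.abs(centroids - centroids[0]).max() < 1.0


class TestRankBackground:
    def test_constant_sequence_reproduced(self):
        frames = np.full((25, 4, 4), 3.7)
        stack = FrameStack(frames, 50.0, (10.0, 10.0))
        bg = preproc.temporal_rank_background(stack)
        np.testing.assert_array_equal(bg.frames, 3.7)

    def test_rank3_ignores_short_transient(self):
        # 3rd smallest over the window skips a 2-frame bright transient
        vals = np.zeros(25)
        vals[10] = 5.0
        vals[11] = 9.0
        frames = np.zeros((25, 1, 1))
        frames[:, 0, 0] = vals
        stack = FrameStack(frames, 50.0, (10.0, 10.0))
        bg = preproc.temporal_rank_background(stack, rank=3, half_window=10)
        assert bg.frames[10, 0, 0] == 0.0
        assert bg.frames[11, 0, 0] == 0.0

    def test_rank_is_order_statistic(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(size=(21, 2, 2))
        stack = FrameStack(frames, 50.0, (10.0, 10.0))
        bg = preproc.temporal_rank_background(stack, rank=3, half_window=10)
        expected = np.sort(frames, axis=0)[2]  # full window at the centre frame
        np.testing.assert_allclose(bg.frames[10], expected)

    def test_bubble_free_phantom_background_is_speckle(self):
        truth = phantom.PhantomTruth(segments=[], bubble_tracks=[], n_frames=25, frame_rate=50.0)
        stack = phantom.render_frames(truth, (232.0, 232.0), background_amplitude=0.4, seed=2)
        bg = preproc.temporal_rank_background(stack)
        np.testing.assert_allclose(bg.frames, stack.frames)

    def test_invalid_rank_rejected(self):
        stack = FrameStack(np.zeros((5, 2, 2)), 50.0, (10.0, 10.0))
        with pytest.raises(ValueError):
            preproc.temporal_rank_background(stack, rank=0)
        with pytest.raises(ValueError):
            preproc.temporal_rank_background(stack, rank=25, half_window=10)


class TestForeground:
    def test_identical_stacks_give_zero(self):
        stack = speckle_stack()
        fg = preproc.foreground(stack, stack)
        np.testing.assert_array_equal(fg.frames, 0.0)

    def test_clipped_at_zero_and_isolates_transient(self):
        base = np.full((21, 3, 3), 1.0)
        base[10, 1, 1] = 4.0
        stack = FrameStack(base, 50.0, (10.0, 10.0))
        bg = preproc.temporal_rank_background(stack)
        fg = preproc.foreground(stack, bg)
        assert fg.frames.min() >= 0.0
        assert fg.frames[10, 1, 1] == pytest.approx(3.0)
        fg.frames[10, 1, 1] = 0.0
        np.testing.assert_array_equal(fg.frames, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            preproc.foreground(speckle_stack(6), speckle_stack(5))


class TestCalibrateThreshold:
    def _fg(self, dead_max):
        frames = np.zeros((30, 4, 4))
        frames[:10] = 2.0  # bubbles before destruction
        frames[10:20] = dead_max  # dead window
        frames[20:] = 2.0
        return FrameStack(frames, 50.0, (10.0, 10.0), destruction_frame=10)

    def test_all_zero_dead_window(self):
        thr = preproc.calibrate_threshold(self._fg(0.0), 10, 10)
        assert 0 < thr < 1e-300

    def test_threshold_just_above_dead_window_max(self):
        thr = preproc.calibrate_threshold(self._fg(0.7), 10, 10)
        assert thr > 0.7
        assert thr == pytest.approx(0.7, rel=1e-12)

    def test_dead_window_yields_zero_detections(self):
        fg = self._fg(0.7)
        thr = preproc.calibrate_threshold(fg, 10, 10)
        roi = np.ones((4, 4), dtype=bool)
        dset = preproc.detect_bubbles(fg, thr, roi, min_pixels=1)
        assert all(not (10 <= d.frame < 20) for d in dset.detections)

    def test_fallback_warns_without_destruction(self):
        fg = FrameStack(np.random.default_rng(0).uniform(size=(30, 4, 4)), 50.0, (10, 10))
        with pytest.warns(UserWarning, match="quantile"):
            thr = preproc.calibrate_threshold(fg, None)
        assert thr > 0


class TestDetectBubbles:
    def _blob_stack(self, centers, shape=(40, 40)):
        frames = np.zeros((2, *shape))
        for r, c in centers:
            frames[:, r - 1 : r + 2, c - 1 : c + 2] = 1.0
            frames[:, r, c] = 3.0
        return FrameStack(frames, 50.0, (11.6, 11.6))

    def test_symmetric_blob_centroid_at_pixel_centre(self):
        stack = self._blob_stack([(10, 14)])
        dset = preproc.detect_bubbles(stack, 0.5, np.ones((40, 40), bool))
        assert len(dset) == 2  # one per frame
        d = dset.detections[0]
        assert d.position == pytest.approx((10 * 11.6, 14 * 11.6))
        assert d.pixel_count == 9

    def test_two_separated_blobs_give_two_detections(self):
        stack = self._blob_stack([(10, 10), (30, 30)])
        dset = preproc.detect_bubbles(stack, 0.5, np.ones((40, 40), bool))
        assert len(dset.by_frame()[0]) == 2

    def test_min_pixels_rejects_specks(self):
        frames = np.zeros((2, 20, 20))
        frames[:, 5, 5] = 10.0  # single-pixel spike
        stack = FrameStack(frames, 50.0, (11.6, 11.6))
        dset = preproc.detect_bubbles(stack, 0.5, np.ones((20, 20), bool), min_pixels=2)
        assert len(dset) == 0

    @pytest.mark.parametrize("thr_pair", [(0.4, 0.8), (0.8, 2.0), (0.4, 2.9)])
    def test_threshold_monotonicity(self, thr_pair):
        lo, hi = thr_pair
        stack = self._blob_stack([(10, 10), (30, 30), (10, 30)])
        roi = np.ones((40, 40), bool)
        n_lo = len(preproc.detect_bubbles(stack, lo, roi))
        n_hi = len(preproc.detect_bubbles(stack, hi, roi))
        assert n_hi <= n_lo

    def test_empty_roi_rejected(self):
        stack = self._blob_stack([(10, 10)])
        with pytest.raises(ValueError):
            preproc.detect_bubbles(stack, 0.5, np.zeros((40, 40), bool))

    def test_excluded_frames_produce_no_detections(self):
        stack = self._blob_stack([(10, 10)])
        motion = MotionEstimate(
            displacement_um=np.zeros((2, 2)),
            correlation=np.ones(2),
            excluded=np.array([False, True]),
        )
        dset = preproc.detect_bubbles(stack, 0.5, np.ones((40, 40), bool), motion=motion)
        assert {d.frame for d in dset.detections} == {0}


class TestEndToEndDetection:
    def test_zero_noise_phantom_perfect_recall(self, recovery_run):
        from mulm.validate import detection_recall

        recall = detection_recall(recovery_run["detections"], recovery_run["truth"])
        assert recall == 1.0

    def test_localization_below_tenth_pixel(self, recovery_run):
        from mulm.validate import match_detections

        match = match_detections(recovery_run["detections"], recovery_run["truth"])
        errors = np.array([e for _, e in match.values()])
        assert errors.mean() < 0.1 * 11.6
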