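"""Phantom generator: geometry, bubble kinematics, rendering physics."""

import numpy as np
import pytest

from mulm import phantom
from mulm.phantom import (
    VesselSegment,
    generate_vessel_network,
    make_motion_profile,
    parallel_vessel_phantom,
    render_frames,
    simulate_bubbles,
)


def one_segment(speed=1.0):
    return VesselSegment(start=(100.0, 100.0), end=(100.0, 900.0), radius=10.0, flow_speed=speed)


class TestVesselNetwork:
    def test_segments_inside_region_and_deterministic(self):
        region = (1000.0, 1000.0)
        a = generate_vessel_network(region, n_segments=1, seed=7)
        b = generate_vessel_network(region, n_segments=1, seed=7)
        for seg in a:
            for p in (seg.start, seg.end):
                assert 0 <= p[0] <= region[0] and 0 <= p[1] <= region[1]
        assert a == b

    def test_radii_within_requested_range(self):
        segs = generate_vessel_network(
            (2000.0, 2000.0), n_segments=20, radius_range_um=(5.0, 40.0), seed=1
        )
        radii = [s.radius for s in segs]
        assert min(radii) >= 5.0 and max(radii) <= 40.0
        assert len(segs) == 20

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError):
            generate_vessel_network((-1.0, 100.0), 1)
        with pytest.raises(ValueError):
            generate_vessel_network((100.0, 100.0), 0)
        with pytest.raises(ValueError):
            generate_vessel_network((100.0, 100.0), 1, radius_range_um=(40.0, 5.0))

    def test_segment_invariants(self):
        with pytest.raises(ValueError):
            VesselSegment(start=(0, 0), end=(0, 0), radius=5.0, flow_speed=1.0)
        with pytest.raises(ValueError):
            VesselSegment(start=(0, 0), end=(1, 1), radius=-1.0, flow_speed=1.0)


class TestSimulateBubbles:
    def test_zero_rate_gives_no_bubbles(self):
        truth = simulate_bubbles([one_segment()], duration_s=1.0, bubble_rate_per_s=0.0)
        assert truth.bubble_tracks == []

    def test_step_is_speed_over_frame_rate(self):
        # 1 mm/s at 50 Hz advances 20 µm per frame
        truth = simulate_bubbles(
            [one_segment(speed=1.0)], duration_s=2.0, frame_rate=50.0,
            bubble_rate_per_s=2.0, seed=0,
        )
        assert truth.bubble_tracks
        for tr in truth.bubble_tracks:
            if len(tr.frames) >= 2:
                steps = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
                gaps = np.diff(tr.frames)
                np.testing.assert_allclose(steps / gaps, 20.0, rtol=1e-9)

    def test_destruction_dead_window_is_empty(self):
        truth = simulate_bubbles(
            [one_segment(speed=0.3)], duration_s=4.0, bubble_rate_per_s=20.0,
            destruction_frame=100, dead_window=10, seed=2,
        )
        for f in range(100, 110):
            assert truth.n_bubbles_at(f) == 0
        assert any(truth.n_bubbles_at(f) for f in range(100))

    def test_timestamps_strictly_increasing(self):
        truth = simulate_bubbles(
            [one_segment()], duration_s=2.0, bubble_rate_per_s=10.0, seed=5
        )
        for tr in truth.bubble_tracks:
            assert np.all(np.diff(tr.frames) > 0)

    def test_dwell_cap_and_uniform_entry(self):
        seg = one_segment(speed=0.5)
        truth = simulate_bubbles(
            [seg], duration_s=4.0, bubble_rate_per_s=10.0,
            entry_mode="uniform", max_dwell_frames=6, seed=4,
        )
        assert truth.bubble_tracks
        starts = []
        for tr in truth.bubble_tracks:
            assert len(tr.frames) <= 6
            starts.append(tr.positions[0, 0 + 1])  # lateral coordinate
        # uniform entry spreads starting points along the vessel
        assert np.ptp(starts) > 0.2 * seg.length

    def test_bubbles_lie_on_vessel(self):
        seg = one_segment()
        truth = simulate_bubbles([seg], duration_s=2.0, bubble_rate_per_s=5.0, seed=1)
        for tr in truth.bubble_tracks:
            assert np.allclose(tr.positions[:, 0], seg.start[0])
            assert np.all(tr.positions[:, 1] >= seg.start[1] - 1e-9)
            assert np.all(tr.positions[:, 1] <= seg.end[1] + 1e-9)


class TestRenderFrames:
    def _static_truth(self, pos=(500.0, 500.0), n_frames=3):
        tr = phantom.BubbleTrack(
            frames=np.arange(n_frames),
            positions=np.tile(np.asarray(pos), (n_frames, 1)),
            segment_index=0,
        )
        return phantom.PhantomTruth(
            segments=[], bubble_tracks=[tr], n_frames=n_frames, frame_rate=50.0
        )

    def test_centroid_of_noiseless_bubble_matches_truth(self):
        truth = self._static_truth(pos=(501.3, 497.2))
        stack = render_frames(truth, (1000.0, 1000.0), background_amplitude=0.0)
        frame = stack.frames[0]
        rr, cc = np.mgrid[: frame.shape[0], : frame.shape[1]]
        w = frame / frame.sum()
        centroid = np.array([(rr * w).sum(), (cc * w).sum()]) * np.array(stack.pixel_spacing)
        assert np.linalg.norm(centroid - np.array([501.3, 497.2])) < 0.01 * 11.6

    def test_static_background_identical_across_frames(self):
        truth = phantom.PhantomTruth(
            segments=[], bubble_tracks=[], n_frames=4, frame_rate=50.0
        )
        stack = render_frames(
            truth, (500.0, 500.0), background_amplitude=0.5, noise_sigma=0.0, seed=9
        )
        for f in range(1, 4):
            np.testing.assert_array_equal(stack.frames[f], stack.frames[0])

    def test_seeded_determinism_bit_identical(self):
        truth = self._static_truth()
        kw = dict(background_amplitude=0.4, noise_sigma=0.1, seed=11)
        a = render_frames(self._static_truth(), (800.0, 800.0), **kw)
        b = render_frames(truth, (800.0, 800.0), **kw)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_total_intensity_proportional_to_bubble_count(self):
        # zero background/noise: frame mass scales with in-field bubbles
        tr1 = phantom.BubbleTrack(
            frames=np.arange(2), positions=np.tile([300.0, 300.0], (2, 1)), segment_index=0
        )
        tr2 = phantom.BubbleTrack(
            frames=np.array([1]), positions=np.array([[700.0, 700.0]]), segment_index=0
        )
        truth = phantom.PhantomTruth(
            segments=[], bubble_tracks=[tr1, tr2], n_frames=2, frame_rate=50.0
        )
        stack = render_frames(truth, (1000.0, 1000.0))
        assert stack.frames[1].sum() == pytest.approx(2 * stack.frames[0].sum(), rel=1e-6)

    def test_noise_toggle_leaves_signal_unchanged(self):
        truth = self._static_truth()
        clean = render_frames(self._static_truth(), (800.0, 800.0),
                              background_amplitude=0.4, noise_sigma=0.0, seed=5)
        noisy = render_frames(truth, (800.0, 800.0),
                              background_amplitude=0.4, noise_sigma=0.05, seed=5)
        diff = noisy.frames - clean.frames
        # where clipping is inactive the residual is exactly the noise field
        active = clean.frames > 0.3
        assert np.abs(diff[active]).max() < 0.05 * 6
        assert diff[active].std() == pytest.approx(0.05, rel=0.1)

    def test_motion_profile_shifts_bubble(self):
        truth = self._static_truth(n_frames=2)
        motion = np.array([[0.0, 0.0], [40.0, -20.0]])
        stack = render_frames(
            truth, (1000.0, 1000.0), motion_profile_um=motion
        )
        peaks = [
            np.unravel_index(np.argmax(stack.frames[f]), stack.frames[f].shape)
            for f in range(2)
        ]
        delta = (np.array(peaks[1]) - np.array(peaks[0])) * np.array(stack.pixel_spacing)
        assert np.linalg.norm(delta - [40.0, -20.0]) < 12.0  # within one pixel


class TestMotionProfile:
    def test_spikes_have_requested_magnitude(self):
        prof = make_motion_profile(50, jitter_sigma_um=1.0, spike_frames=(10, 30),
                                   spike_magnitude_um=80.0, seed=0)
        mags = np.linalg.norm(prof, axis=1)
        assert mags[10] == pytest.approx(80.0)
        assert mags[30] == pytest.approx(80.0)
        assert np.median(mags) < 5.0


class TestParallelPhantom:
    def test_designed_passage_counts_and_speeds(self):
        speeds = [0.4, 0.8]
        truth, region = parallel_vessel_phantom(speeds, n_bubbles_per_vessel=3)
        per_vessel = {}
        for tr in truth.bubble_tracks:
            per_vessel.setdefault(tr.segment_index, []).append(tr)
        assert {len(v) for v in per_vessel.values()} == {3}
        for si, trs in per_vessel.items():
            step = speeds[si] * 1000.0 / truth.frame_rate
            for tr in trs:
                d = np.diff(tr.positions[:, 1])
                np.testing.assert_allclose(d, step, rtol=1e-9)
        # no two bubbles of one vessel coexist
        for si, trs in per_vessel.items():
            frames = np.concatenate([t.frames for t in trs])
            assert len(frames) == len(set(frames.tolist()))
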