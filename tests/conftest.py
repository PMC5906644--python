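"""Shared fixtures: detection-set builders and phantom pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from mulm import mcmcda, phantom, preproc, superres
from mulm.core import Detection, DetectionSet


def build_detection_set(
    points: list[tuple[int, float, float]],
    frame_rate: float = 50.0,
    roi_area_um2: float = 1.0e6,
    n_frames: int | None = None,
) -> DetectionSet:
    """DetectionSet from (frame, axial µm, lateral µm) triples."""
    dets = [
        Detection(frame=f, position=(a, l), total_intensity=1.0, pixel_count=2)
        for f, a, l in points
    ]
    if n_frames is None:
        n_frames = max(p[0] for p in points) + 1 if points else 1
    return DetectionSet(
        detections=dets,
        n_frames=n_frames,
        frame_rate=frame_rate,
        roi_area_um2=roi_area_um2,
    )


@pytest.fixture(scope="session")
def dset_builder():
    return build_detection_set


def random_tiny_instance(seed: int) -> DetectionSet:
    """A random tracking instance with ≤ 10 detections over ≤ 4 frames."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 11))
    points = [
        (int(rng.integers(0, 4)), float(rng.uniform(0, 400)), float(rng.uniform(0, 400)))
        for _ in range(n)
    ]
    return build_detection_set(points)


@pytest.fixture(scope="session")
def tiny_instance_factory():
    return random_tiny_instance


@pytest.fixture(scope="session")
def recovery_run():
    """Zero-noise, motion-free recovery experiment on ten parallel vessels.

    Ten straight vessels at designed speeds 0.3–1.2 mm s⁻¹ are rendered,
    detected, tracked and rasterized once per session; tests assert
    recall, link accuracy, speed recovery and map resolution on it.
    """
    speeds = [0.3 + 0.1 * k for k in range(10)]
    truth, region = phantom.parallel_vessel_phantom(speeds)
    stack = phantom.render_frames(
        truth, region, background_amplitude=0.3, noise_sigma=0.0, seed=3
    )
    motion = preproc.estimate_rigid_motion(stack)
    motion = preproc.exclude_frames(motion)
    compensated = preproc.compensate_motion(stack, motion)
    background = preproc.temporal_rank_background(compensated)
    fg = preproc.foreground(compensated, background)
    roi = np.ones(stack.shape, dtype=bool)
    dset = preproc.detect_bubbles(fg, threshold=0.15, roi=roi, min_pixels=2, motion=motion)
    assoc = mcmcda.run_mcmcda(
        dset, mcmcda.MotionModelParams(), n_iterations=400_000, seed=7
    )
    tracks = mcmcda.tracks_to_kinematics(assoc)
    grid = superres.GridSpec.covering(region)
    maps = superres.rasterize_tracks(tracks, grid)
    return {
        "speeds": speeds,
        "truth": truth,
        "region": region,
        "stack": stack,
        "motion": motion,
        "foreground": fg,
        "detections": dset,
        "association": assoc,
        "tracks": tracks,
        "maps": maps,
    }
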