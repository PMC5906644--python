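"""Detection preprocessing: motion handling and bubble localization.

The chain mirrors standard contrast-microbubble processing: rigid
in-plane motion is estimated by upsampled phase cross-correlation
against a reference frame and compensated by sub-pixel interpolation;
frames with large displacements or strong decorrelation (out-of-plane
breathing motion) are excluded outright.  The static tissue background
is estimated per pixel with a temporal rank filter (rank 3 over ±10
frames by default) and subtracted; an adaptive intensity threshold is
calibrated so that the frames immediately after a destruction pulse —
which contain no bubbles — yield zero detections.  Each supra-threshold
connected component becomes one detection localized at its
intensity-weighted centroid, sub-pixel.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.registration import phase_cross_correlation

from .core import Detection, DetectionSet, FrameStack, MotionEstimate

__all__ = [
    "estimate_rigid_motion",
    "exclude_frames",
    "compensate_motion",
    "temporal_rank_background",
    "foreground",
    "calibrate_threshold",
    "detect_bubbles",
    "roi_mask_from_polygon",
]

# 8-connectivity for connected components; single bubbles blur across
# diagonals through the anisotropic PSF.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def estimate_rigid_motion(
    stack: FrameStack,
    upsample_factor: int = 4,
    reference: int = 0,
) -> MotionEstimate:
    """Estimate per-frame rigid translation against a reference frame.

    Uses phase cross-correlation on an ``upsample_factor``-fold finer
    grid, so displacements are resolved to ``pixel_spacing /
    upsample_factor``.  The Pearson correlation of each registered frame
    with the reference is recorded; blank (zero-variance) frames have
    undefined correlation and are flagged excluded immediately.
    """
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    n = stack.n_frames
    ref = stack.frames[reference]
    spacing = np.asarray(stack.pixel_spacing)
    disp = np.zeros((n, 2))
    corr = np.ones(n)
    excluded = np.zeros(n, dtype=bool)
    ref_sd = ref.std()
    for t in range(n):
        if t == reference:
            continue
        frame = stack.frames[t]
        if frame.std() == 0 or ref_sd == 0:
            corr[t] = np.nan
            excluded[t] = True
            continue
        shift_px, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        # shift_px registers `frame` onto `ref`; the frame's displacement
        # relative to the reference is the opposite sign
        disp[t] = -shift_px * spacing
        registered = ndimage.shift(frame, shift_px, order=1, mode="nearest")
        corr[t] = float(np.corrcoef(ref.ravel(), registered.ravel())[0, 1])
    return MotionEstimate(
        displacement_um=disp, correlation=corr, excluded=excluded, reference=reference
    )


def exclude_frames(
    motion: MotionEstimate,
    displacement_limit_um: float = 40.0,
    correlation_floor: float = 0.8,
) -> MotionEstimate:
    """Mark frames with large displacement or low correlation as excluded.

    Breathing spikes show up as displacement outliers accompanied by
    decorrelation, indicating out-of-plane movement no in-plane
    correction can fix; those frames are dropped rather than corrected.
    Already-excluded frames stay excluded.
    """
    mag = np.linalg.norm(motion.displacement_um, axis=1)
    with np.errstate(invalid="ignore"):
        bad = (mag > displacement_limit_um) | (motion.correlation < correlation_floor)
    bad |= np.isnan(motion.correlation)
    excluded = motion.excluded | bad
    if excluded.all():
        raise RuntimeError("no usable frames: every frame excluded by motion criteria")
    return MotionEstimate(
        displacement_um=motion.displacement_um,
        correlation=motion.correlation,
        excluded=excluded,
        reference=motion.reference,
    )


def compensate_motion(stack: FrameStack, motion: MotionEstimate) -> FrameStack:
    """Translate each retained frame back by its estimated displacement.

    Sub-pixel interpolation (cubic spline).  Excluded frames are passed
    through untouched so frame indexing is preserved; downstream stages
    skip them via the motion estimate.
    """
    if motion.n_frames != stack.n_frames:
        raise ValueError("motion estimate does not cover the stack")
    spacing = np.asarray(stack.pixel_spacing)
    out = stack.frames.copy()
    for t in range(stack.n_frames):
        if motion.excluded[t]:
            continue
        shift_px = -motion.displacement_um[t] / spacing
        if np.any(shift_px != 0):
            out[t] = ndimage.shift(stack.frames[t], shift_px, order=3, mode="nearest")
    return stack.copy_with(np.clip(out, 0.0, None))


def temporal_rank_background(
    stack: FrameStack, rank: int = 3, half_window: int = 10
) -> FrameStack:
    """Per-pixel temporal rank filter estimating the static background.

    For every pixel and frame the background is the ``rank``-th smallest
    value over the ``±half_window`` temporal window centred on that
    frame (truncated at the sequence ends; the rank is clamped to the
    truncated window length).  A low rank keeps transient bright bubbles
    out of the background while tolerating a few dark outliers.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    n = stack.n_frames
    if rank < 1 or rank > 2 * half_window + 1:
        raise ValueError("rank must lie within the full window length")
    if n < rank:
        raise ValueError("sequence shorter than the requested rank")
    bg = np.empty_like(stack.frames)
    for t in range(n):
        lo = max(0, t - half_window)
        hi = min(n, t + half_window + 1)
        window = stack.frames[lo:hi]
        k = min(rank, window.shape[0]) - 1
        bg[t] = np.partition(window, k, axis=0)[k]
    return stack.copy_with(bg)


def foreground(stack: FrameStack, background: FrameStack) -> FrameStack:
    """Original minus background, clipped at zero."""
    if stack.frames.shape != background.frames.shape:
        raise ValueError("stack and background shapes differ")
    return stack.copy_with(np.clip(stack.frames - background.frames, 0.0, None))


def calibrate_threshold(
    fg: FrameStack,
    destruction_frame: int | None = None,
    dead_window: int = 10,
    roi: np.ndarray | None = None,
    fallback_quantile: float = 0.999,
    fallback_frames: int = 20,
) -> float:
    """Adapt the detection threshold to the destruction event.

    Returns the smallest threshold for which the bubble-free frames
    immediately after the destruction pulse yield zero detections: just
    above the maximum foreground value observed in those frames (inside
    the ROI if one is given).  Without a destruction event, falls back to
    a high quantile of the foreground over the earliest frames, with a
    warning — a heuristic, not a calibration.
    """
    if destruction_frame is not None:
        lo, hi = destruction_frame, destruction_frame + dead_window
        if hi > fg.n_frames:
            raise ValueError("dead window extends past the end of the sequence")
        block = fg.frames[lo:hi]
    else:
        warnings.warn(
            "no destruction event: falling back to a quantile threshold",
            stacklevel=2,
        )
        block = fg.frames[: max(2, fallback_frames)]
    if roi is not None:
        block = block[:, roi]
    if destruction_frame is not None:
        m = float(block.max())
    else:
        m = float(np.quantile(block, fallback_quantile))
    if m <= 0:
        return float(np.nextafter(0.0, 1.0))
    return float(np.nextafter(m, np.inf))


def detect_bubbles(
    fg: FrameStack,
    threshold: float,
    roi: np.ndarray,
    min_pixels: int = 2,
    motion: MotionEstimate | None = None,
) -> DetectionSet:
    """Localize bubbles as intensity-weighted centroids of bright blobs.

    Per retained frame, pixels with foreground strictly above
    ``threshold`` inside the ROI are grouped into 8-connected
    components; each component of at least ``min_pixels`` pixels becomes
    one detection positioned at the intensity-weighted centroid in µm
    (sub-pixel).  Components touching the ROI boundary are kept.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != fg.shape:
        raise ValueError("ROI mask shape must match the frames")
    if not roi.any():
        raise ValueError("empty ROI")
    spacing = np.asarray(fg.pixel_spacing)
    retained = (
        range(fg.n_frames) if motion is None else motion.retained_indices()
    )
    detections: list[Detection] = []
    for t in retained:
        mask = (fg.frames[t] > threshold) & roi
        if not mask.any():
            continue
        labels, n_comp = ndimage.label(mask, structure=_STRUCTURE_8)
        intens = fg.frames[t]
        for comp in range(1, n_comp + 1):
            rr, cc = np.nonzero(labels == comp)
            if rr.size < min_pixels:
                continue
            w = intens[rr, cc]
            total = float(w.sum())
            centroid_px = np.array([np.average(rr, weights=w), np.average(cc, weights=w)])
            pos = centroid_px * spacing
            detections.append(
                Detection(
                    frame=int(t),
                    position=(float(pos[0]), float(pos[1])),
                    total_intensity=total,
                    pixel_count=int(rr.size),
                )
            )
    roi_area = float(roi.sum()) * float(spacing[0] * spacing[1])
    return DetectionSet(
        detections=detections,
        n_frames=fg.n_frames,
        frame_rate=fg.frame_rate,
        roi_area_um2=roi_area,
        roi_mask=roi,
    )


def roi_mask_from_polygon(
    vertices_um: np.ndarray,
    shape: tuple[int, int],
    pixel_spacing: tuple[float, float],
) -> np.ndarray:
    """Rasterize an (axial, lateral) µm polygon to a pixel mask."""
    verts = np.asarray(vertices_um, dtype=float) / np.asarray(pixel_spacing)
    return polygon2mask(shape, verts)
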