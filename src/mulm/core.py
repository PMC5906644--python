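"""Shared data containers and the coordinate convention.

All physical positions are expressed in micrometres (µm) as ``(axial,
lateral)`` pairs, i.e. in (row, column) order of the underlying image
arrays.  The origin sits at the centre of pixel ``(0, 0)``; pixel ``(r, c)``
therefore has its centre at ``(r * axial_spacing, c * lateral_spacing)``.
Indices are 0-based.  Speeds are reported in mm s⁻¹; internally the
tracking code works in µm per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FrameStack",
    "MotionEstimate",
    "Detection",
    "DetectionSet",
    "pixel_to_um",
    "um_to_pixel",
]


def pixel_to_um(rc: np.ndarray, pixel_spacing: tuple[float, float]) -> np.ndarray:
    """Convert fractional (row, col) pixel coordinates to (axial, lateral) µm."""
    rc = np.asarray(rc, dtype=float)
    return rc * np.asarray(pixel_spacing, dtype=float)


def um_to_pixel(pos: np.ndarray, pixel_spacing: tuple[float, float]) -> np.ndarray:
    """Convert (axial, lateral) µm positions to fractional (row, col) pixels."""
    pos = np.asarray(pos, dtype=float)
    return pos / np.asarray(pixel_spacing, dtype=float)


@dataclass
class FrameStack:
    """A time-ordered stack of 2-D B-mode intensity frames with calibration.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)`` with non-negative
        intensities.
    frame_rate
        Acquisition rate in Hz.
    pixel_spacing
        ``(axial, lateral)`` pixel pitch in µm.
    destruction_frame
        Index of the frame at which a destructive pulse cleared the
        imaging plane of microbubbles, if such an event was recorded.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_spacing: tuple[float, float]
    destruction_frame: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (time, rows, cols) array with >= 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        sp = tuple(float(s) for s in self.pixel_spacing)
        if len(sp) != 2 or min(sp) <= 0:
            raise ValueError("pixel_spacing must be two positive values (axial, lateral)")
        self.pixel_spacing = sp

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def copy_with(self, frames: np.ndarray) -> "FrameStack":
        return FrameStack(
            frames=frames,
            frame_rate=self.frame_rate,
            pixel_spacing=self.pixel_spacing,
            destruction_frame=self.destruction_frame,
        )


@dataclass
class MotionEstimate:
    """Per-frame rigid in-plane displacement relative to a reference frame.

    ``displacement_um[t]`` is the (axial, lateral) shift of frame ``t``
    with respect to the reference; the reference frame has displacement
    ``(0, 0)`` by construction.  ``correlation[t]`` is the Pearson
    similarity of the shifted frame with the reference, used to spot
    out-of-plane decorrelation.  ``excluded[t]`` marks frames dropped
    from all downstream processing.
    """

    displacement_um: np.ndarray  # (n_frames, 2)
    correlation: np.ndarray  # (n_frames,)
    excluded: np.ndarray  # (n_frames,) bool
    reference: int = 0

    def __post_init__(self) -> None:
        self.displacement_um = np.asarray(self.displacement_um, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        n = self.displacement_um.shape[0]
        if self.correlation.shape != (n,) or self.excluded.shape != (n,):
            raise ValueError("motion fields must share the frame count")

    @property
    def n_frames(self) -> int:
        return self.displacement_um.shape[0]

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)


@dataclass(frozen=True)
class Detection:
    """One localized microbubble echo.

    ``position`` is the intensity-weighted centroid in µm (axial, lateral),
    sub-pixel by construction.
    """

    frame: int
    position: tuple[float, float]
    total_intensity: float
    pixel_count: int

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class DetectionSet:
    """All microbubble detections of a sequence, grouped by frame.

    These are the measured positions handed to the data-association
    tracker.  ``roi_area_um2`` is the area of the analysis region and
    normalizes the uniform position density used for clutter and for
    track births.
    """

    detections: list[Detection]
    n_frames: int
    frame_rate: float
    roi_area_um2: float
    roi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.detections = sorted(
            self.detections, key=lambda d: (d.frame, d.position[0], d.position[1])
        )
        if self.roi_area_um2 <= 0:
            raise ValueError("roi_area_um2 must be positive")

    def __len__(self) -> int:
        return len(self.detections)

    def by_frame(self) -> dict[int, list[Detection]]:
        out: dict[int, list[Detection]] = {}
        for d in self.detections:
            out.setdefault(d.frame, []).append(d)
        return out

    def positions(self) -> np.ndarray:
        if not self.detections:
            return np.empty((0, 2))
        return np.array([d.position for d in self.detections], dtype=float)
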