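"""Conventional CEUS reference analyses: MIOT and replenishment kinetics.

Maximum Intensity Over Time (MIOT) projects the per-pixel temporal
maximum of the contrast sequence after subtracting the per-pixel
temporal median (the static background) and segments it inside the ROI;
the segmented fraction is a voxel-scale relative blood volume that is
expected to overestimate the track-based rBV, since every bubble is
smeared over the point-spread function rather than a 5 µm track.

Destruction–replenishment analysis fits the mean ROI intensity after a
destructive pulse to the Wei model A·(1 − exp(−β t)); β times an
effective beam-width constant is a (known-to-be-low) velocity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .core import FrameStack

__all__ = [
    "MiotResult",
    "ReplenishmentFit",
    "miot_rbv",
    "fit_replenishment",
    "fit_replenishment_curve",
    "wei_model",
]


@dataclass
class MiotResult:
    miot_image: np.ndarray
    vessel_mask: np.ndarray
    rbv: float


@dataclass
class ReplenishmentFit:
    """Wei-model fit of a replenishment curve.

    ``velocity_proxy`` = rate_beta × beam_width_mm converts the refill
    rate to mm s⁻¹ through an effective beam elevation width; the
    conversion ignores the true beam profile and systematically
    underestimates in-plane bubble speeds.
    """

    plateau_A: float
    rate_beta: float
    velocity_proxy: float
    fit_rmse: float
    converged: bool
    times_s: np.ndarray
    curve: np.ndarray


def miot_rbv(
    stack: FrameStack,
    roi: np.ndarray,
    seg_threshold: float | None = None,
) -> MiotResult:
    """Maximum-intensity-over-time rBV inside a ROI.

    The MIOT image is the per-pixel temporal maximum minus the
    per-pixel temporal median.  Segmentation uses ``seg_threshold`` if
    given, else Otsu's threshold over the ROI.  Both max and median are
    symmetric in time, so the result is invariant to frame order.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    miot = stack.frames.max(axis=0) - np.median(stack.frames, axis=0)
    vals = miot[roi]
    if seg_threshold is None:
        if np.allclose(vals, vals.flat[0]):
            seg_threshold = float(vals.flat[0])  # constant: nothing to segment
        else:
            seg_threshold = float(threshold_otsu(vals))
    vessel_mask = roi & (miot > seg_threshold)
    return MiotResult(
        miot_image=miot,
        vessel_mask=vessel_mask,
        rbv=float(vessel_mask.sum() / roi.sum()),
    )


def wei_model(t: np.ndarray, plateau: float, beta: float) -> np.ndarray:
    """Replenishment curve A·(1 − e^(−βt))."""
    return plateau * (1.0 - np.exp(-beta * t))


def fit_replenishment_curve(
    times_s: np.ndarray,
    curve: np.ndarray,
    beam_width_mm: float = 1.0,
) -> ReplenishmentFit:
    """Fit an intensity time-curve to the Wei model A·(1 − e^(−βt)).

    A fit that fails to converge or explains the curve poorly is
    reported with ``converged=False`` rather than raised — noisy
    clinical replenishment curves frequently cannot be fitted.
    """
    times = np.asarray(times_s, dtype=float)
    curve = np.asarray(curve, dtype=float)
    converged = True
    try:
        k = min(10, len(curve) - 1)
        slope0 = max((curve[k] - curve[0]) / max(times[k], 1e-9), 1e-6)
        a0 = max(float(curve.max()), 1e-6)
        p0 = (a0, min(max(slope0 / a0, 1e-3), 10.0))
        popt, _ = curve_fit(
            wei_model,
            times,
            curve,
            p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        plateau, beta = float(popt[0]), float(popt[1])
    except (RuntimeError, ValueError):
        plateau, beta, converged = 0.0, 0.0, False

    resid = curve - wei_model(times, plateau, beta)
    rmse = float(np.sqrt(np.mean(resid**2)))
    if converged and (plateau <= 0 or beta <= 1e-9 or rmse > max(0.5 * abs(plateau), 1e-12)):
        converged = False
    return ReplenishmentFit(
        plateau_A=plateau,
        rate_beta=beta,
        velocity_proxy=beta * beam_width_mm,
        fit_rmse=rmse,
        converged=converged,
        times_s=times,
        curve=curve,
    )


def fit_replenishment(
    stack: FrameStack,
    roi: np.ndarray,
    destruction_frame: int | None = None,
    dead_window: int = 0,
    beam_width_mm: float = 1.0,
    background: np.ndarray | None = None,
) -> ReplenishmentFit:
    """Fit the post-destruction mean-ROI intensity to the Wei model.

    The curve starts at the end of the destruction dead window; its
    baseline (first sample) is subtracted before fitting.
    """
    if destruction_frame is None:
        destruction_frame = stack.destruction_frame
    if destruction_frame is None:
        raise ValueError("no destruction frame available")
    start = destruction_frame + dead_window
    n_post = stack.n_frames - start
    if n_post < 5 * stack.frame_rate:
        raise ValueError("need at least 5 s of post-destruction data")
    roi = np.asarray(roi, dtype=bool)
    frames = stack.frames[start:]
    if background is not None:
        frames = np.clip(frames - background[None], 0.0, None)
    curve = frames[:, roi].mean(axis=1)
    curve = curve - curve[0]
    times = np.arange(n_post) / stack.frame_rate
    return fit_replenishment_curve(times, curve, beam_width_mm)
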