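"""Scalar vascular parameters extracted from the super-resolution maps.

Per analysis region (core by default, to exclude the large feeding
vessels of the rim) the following are computed: the relative blood
volume (rBV, fraction of the region covered by tracks); mean, variance,
maximum and median of the Euclidean distance from each region pixel to
the closest vessel; the same four statistics of the flow speeds on
vessel pixels; the distance statistics recomputed against only the
slow- or only the fast-flowing vessels (threshold 0.7 mm s⁻¹); and the
local flow-direction entropy, the mean Shannon entropy of the direction
histogram over 25 µm × 25 µm sub-regions — low where flow is locally
ordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from .superres import SuperResMaps

__all__ = [
    "VascularParamSet",
    "compute_rbv",
    "distance_map",
    "distance_stats",
    "velocity_stats",
    "stratify_by_velocity",
    "direction_entropy",
    "compute_parameters",
]

VELOCITY_THRESHOLD_MM_S = 0.7
SUBREGION_SIZE_UM = 25.0
N_DIRECTION_BINS = 8


@dataclass
class VascularParamSet:
    """One tumor's vascular parameter vector for one region.

    Distances in µm (variances µm²), speeds in mm s⁻¹ (variances
    squared), entropy in bits.  Stratified distance statistics are NaN
    when the corresponding velocity stratum is empty.
    """

    region: str
    rbv: float
    dist_mean: float
    dist_var: float
    dist_max: float
    dist_median: float
    vel_mean: float
    vel_var: float
    vel_max: float
    vel_median: float
    distlow_mean: float
    distlow_var: float
    distlow_max: float
    distlow_median: float
    disthigh_mean: float
    disthigh_var: float
    disthigh_max: float
    disthigh_median: float
    direction_entropy: float

    def as_dict(self) -> dict[str, float | str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_rbv(track_map: np.ndarray, region_mask: np.ndarray) -> float:
    """Fraction of the region covered by vessel tracks."""
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    return float((np.asarray(track_map, dtype=bool) & region).sum() / region.sum())


def distance_map(
    track_map: np.ndarray,
    pixel_size_um: float,
    region_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Euclidean distance (µm) from every pixel to the nearest track pixel.

    Track pixels map to 0.  The transform runs on the full grid (the
    nearest vessel may lie outside the region); the region mask only
    restricts which pixels are returned as finite values.
    """
    track = np.asarray(track_map, dtype=bool)
    if not track.any():
        raise ValueError("no vessels detected: empty track map")
    dmap = ndimage.distance_transform_edt(~track) * pixel_size_um
    if region_mask is not None:
        out = np.full(dmap.shape, np.nan)
        out[np.asarray(region_mask, dtype=bool)] = dmap[np.asarray(region_mask, dtype=bool)]
        return out
    return dmap


def _four_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    # population variance: the pixel set is the whole population
    return (
        float(values.mean()),
        float(values.var()),
        float(values.max()),
        float(np.median(values)),
    )


def distance_stats(
    dmap: np.ndarray, region_mask: np.ndarray
) -> tuple[float, float, float, float]:
    """(mean, variance, max, median) of distances over region pixels."""
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    vals = np.asarray(dmap, dtype=float)[region]
    vals = vals[np.isfinite(vals)]
    return _four_stats(vals)


def velocity_stats(
    velocity_map: np.ndarray, track_map: np.ndarray, region_mask: np.ndarray
) -> tuple[float, float, float, float]:
    """(mean, variance, max, median) of flow speeds on in-region vessels."""
    on = np.asarray(track_map, dtype=bool) & np.asarray(region_mask, dtype=bool)
    if not on.any():
        return (math.nan,) * 4
    return _four_stats(np.asarray(velocity_map, dtype=float)[on])


def stratify_by_velocity(
    maps: SuperResMaps, threshold_mm_s: float = VELOCITY_THRESHOLD_MM_S
) -> tuple[np.ndarray, np.ndarray]:
    """Split the track map into slow (< threshold) and fast (≥) vessels."""
    if threshold_mm_s <= 0:
        raise ValueError("threshold must be positive")
    on = maps.track_map
    low = on & (maps.velocity_map < threshold_mm_s)
    high = on & (maps.velocity_map >= threshold_mm_s)
    return low, high


def cohort_velocity_threshold(median_velocities: np.ndarray) -> float:
    """Threshold between slow and fast flow for a cohort: the mean of the
    per-tumor median velocities."""
    return float(np.asarray(median_velocities, dtype=float).mean())


def direction_entropy(
    direction_map: np.ndarray,
    track_map: np.ndarray,
    region_mask: np.ndarray,
    pixel_size_um: float,
    subregion_size_um: float = SUBREGION_SIZE_UM,
    n_bins: int = N_DIRECTION_BINS,
) -> float:
    """Mean local Shannon entropy (bits) of flow directions.

    The region is tiled into ``subregion_size_um`` squares; per tile the
    directions of in-region track pixels are histogrammed over
    ``n_bins`` equal angular bins of (−π, π] and the base-2 entropy
    computed.  Tiles without track pixels do not contribute.  Bounded by
    log2(n_bins); locally ordered flow gives low values.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    step = subregion_size_um / pixel_size_um
    if abs(step - round(step)) > 1e-9:
        raise ValueError("subregion_size_um must be a multiple of the pixel size")
    step = int(round(step))
    on = np.asarray(track_map, dtype=bool) & np.asarray(region_mask, dtype=bool)
    if not on.any():
        return math.nan
    dirs = np.asarray(direction_map, dtype=float)
    rows, cols = on.shape
    edges = np.linspace(-math.pi, math.pi, n_bins + 1)
    entropies: list[float] = []
    for r0 in range(0, rows, step):
        for c0 in range(0, cols, step):
            tile = on[r0 : r0 + step, c0 : c0 + step]
            if not tile.any():
                continue
            vals = dirs[r0 : r0 + step, c0 : c0 + step][tile]
            # map the closed bin edge so −π and π share a bin
            vals = np.where(vals <= -math.pi + 1e-12, math.pi, vals)
            hist, _ = np.histogram(vals, bins=edges)
            p = hist[hist > 0] / hist.sum()
            entropies.append(float(-(p * np.log2(p)).sum()))
    return float(np.mean(entropies))


def compute_parameters(
    maps: SuperResMaps,
    region: str = "core",
    velocity_threshold_mm_s: float = VELOCITY_THRESHOLD_MM_S,
    subregion_size_um: float = SUBREGION_SIZE_UM,
    n_bins: int = N_DIRECTION_BINS,
) -> VascularParamSet:
    """Assemble the full parameter vector for one region of one tumor."""
    masks = {"rim": maps.rim_mask, "core": maps.core_mask, "whole": maps.roi_mask}
    if region not in masks:
        raise ValueError("region must be rim, core or whole")
    region_mask = masks[region]
    if region_mask is None:
        raise ValueError(f"mask for region '{region}' is not set on the maps")
    px = maps.pixel_size_um

    rbv = compute_rbv(maps.track_map, region_mask)
    dmap = distance_map(maps.track_map, px)
    d_stats = distance_stats(dmap, region_mask)
    v_stats = velocity_stats(maps.velocity_map, maps.track_map, region_mask)
    low, high = stratify_by_velocity(maps, velocity_threshold_mm_s)

    def strat_stats(strat_map: np.ndarray) -> tuple[float, float, float, float]:
        if not strat_map.any():
            return (math.nan,) * 4
        return distance_stats(distance_map(strat_map, px), region_mask)

    dl = strat_stats(low)
    dh = strat_stats(high)
    ent = direction_entropy(
        maps.direction_map, maps.track_map, region_mask, px, subregion_size_um, n_bins
    )
    return VascularParamSet(
        region=region,
        rbv=rbv,
        dist_mean=d_stats[0],
        dist_var=d_stats[1],
        dist_max=d_stats[2],
        dist_median=d_stats[3],
        vel_mean=v_stats[0],
        vel_var=v_stats[1],
        vel_max=v_stats[2],
        vel_median=v_stats[3],
        distlow_mean=dl[0],
        distlow_var=dl[1],
        distlow_max=dl[2],
        distlow_median=dl[3],
        disthigh_mean=dh[0],
        disthigh_var=dh[1],
        disthigh_max=dh[2],
        disthigh_median=dh[3],
        direction_entropy=ent,
    )
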