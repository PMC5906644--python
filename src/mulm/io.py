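"""Reading and writing of the pipeline's file formats.

Frame stacks travel as multi-page TIFF with a JSON sidecar carrying the
calibration (frame rate, pixel spacing, destruction frame); detections
and tracks as CSV; ROI polygons as CSV/JSON vertex lists; the
super-resolution maps as 32-bit TIFF per map with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Detection, DetectionSet, FrameStack
from .mcmcda import Association, Track
from .superres import GridSpec, SuperResMaps

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "read_roi_polygon",
    "write_detections",
    "read_detections",
    "write_tracks",
    "write_maps",
    "write_association_summary",
]


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "frame_rate": stack.frame_rate,
        "pixel_spacing_um": list(stack.pixel_spacing),
        "destruction_frame": stack.destruction_frame,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FrameStack(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        pixel_spacing=tuple(meta["pixel_spacing_um"]),
        destruction_frame=meta.get("destruction_frame"),
    )


def read_roi_polygon(path: str | Path) -> np.ndarray:
    """(n, 2) array of (axial, lateral) µm vertices from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return np.asarray(data["vertices_um"], dtype=float)
    df = pd.read_csv(path)
    return df[["axial_um", "lateral_um"]].to_numpy(float)


def write_detections(dset: DetectionSet, path: str | Path) -> None:
    rows = [
        {
            "frame": d.frame,
            "axial_um": d.position[0],
            "lateral_um": d.position[1],
            "intensity": d.total_intensity,
            "pixels": d.pixel_count,
        }
        for d in dset.detections
    ]
    pd.DataFrame(rows, columns=["frame", "axial_um", "lateral_um", "intensity", "pixels"]).to_csv(
        path, index=False
    )


def read_detections(
    path: str | Path, n_frames: int, frame_rate: float, roi_area_um2: float
) -> DetectionSet:
    df = pd.read_csv(path)
    dets = [
        Detection(
            frame=int(r.frame),
            position=(float(r.axial_um), float(r.lateral_um)),
            total_intensity=float(r.intensity),
            pixel_count=int(r.pixels),
        )
        for r in df.itertuples()
    ]
    return DetectionSet(
        detections=dets,
        n_frames=n_frames,
        frame_rate=frame_rate,
        roi_area_um2=roi_area_um2,
    )


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    rows = []
    for tid, tr in enumerate(tracks):
        for k, det in enumerate(tr.detections):
            step = min(k, len(tr.detections) - 2)
            rows.append(
                {
                    "track_id": tid,
                    "frame": det.frame,
                    "axial_um": det.position[0],
                    "lateral_um": det.position[1],
                    "v_axial_mm_s": tr.step_velocities[step, 0],
                    "v_lateral_mm_s": tr.step_velocities[step, 1],
                }
            )
    pd.DataFrame(
        rows,
        columns=["track_id", "frame", "axial_um", "lateral_um", "v_axial_mm_s", "v_lateral_mm_s"],
    ).to_csv(path, index=False)


def write_association_summary(assoc: Association, path: str | Path) -> None:
    summary = {
        "n_detections": len(assoc.detection_set),
        "n_tracks": len(assoc.tracks),
        "n_false_alarms": len(assoc.false_alarms),
        "log_likelihood": assoc.log_likelihood,
        "log_prior": assoc.log_prior,
        "log_posterior": assoc.log_posterior,
    }
    Path(path).write_text(json.dumps(summary, indent=2))


def write_maps(maps: SuperResMaps, out_dir: str | Path, prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{prefix}track_map.tif", maps.track_map.astype(np.float32))
    tifffile.imwrite(out / f"{prefix}velocity_map.tif", maps.velocity_map.astype(np.float32))
    tifffile.imwrite(out / f"{prefix}direction_map.tif", maps.direction_map.astype(np.float32))
    tifffile.imwrite(out / f"{prefix}count_map.tif", maps.count_map.astype(np.float32))
    sidecar = {
        "pixel_size_um": maps.pixel_size_um,
        "origin_um": list(maps.grid.origin_um),
        "shape": list(maps.grid.shape),
    }
    for name in ("roi_mask", "rim_mask", "core_mask"):
        mask = getattr(maps, name)
        if mask is not None:
            tifffile.imwrite(out / f"{prefix}{name}.tif", mask.astype(np.uint8))
            sidecar[name] = f"{prefix}{name}.tif"
    (out / f"{prefix}maps.json").write_text(json.dumps(sidecar, indent=2))
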