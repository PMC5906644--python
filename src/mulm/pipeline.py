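"""End-to-end orchestration: phantom/input → detections → tracks → maps →
parameters → reference analyses, with a machine-readable manifest.

Every stage consumes the previous stage's in-memory objects and writes
its artifact to the output directory; the manifest records the full
configuration, the published-profile constants, and per-stage counts so
a run is auditable and reproducible from its seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import mcmcda, params, phantom, preproc, refmethods, superres
from .config import RunConfig
from .core import DetectionSet, FrameStack, MotionEstimate

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    config: RunConfig
    stack: FrameStack
    truth: phantom.PhantomTruth | None
    motion: MotionEstimate
    detections: DetectionSet
    association: mcmcda.Association
    tracks: list[mcmcda.Track]
    maps: superres.SuperResMaps
    parameters: params.VascularParamSet
    miot: refmethods.MiotResult | None
    replenishment: refmethods.ReplenishmentFit | None
    manifest: dict
    output_dir: Path


def _build_phantom(cfg: RunConfig) -> tuple[FrameStack, phantom.PhantomTruth]:
    ph = cfg.phantom
    segments = phantom.generate_vessel_network(
        ph.region_size_um,
        ph.n_segments,
        ph.radius_range_um,
        ph.speed_range_mm_s,
        seed=cfg.stage_seed("phantom_network"),
    )
    truth = phantom.simulate_bubbles(
        segments,
        ph.duration_s,
        ph.frame_rate,
        ph.bubble_rate_per_s,
        destruction_frame=ph.destruction_frame,
        dead_window=ph.dead_window,
        lateral_dispersion=ph.lateral_dispersion,
        seed=cfg.stage_seed("phantom_bubbles"),
    )
    motion = phantom.make_motion_profile(
        truth.n_frames,
        jitter_sigma_um=ph.jitter_sigma_um,
        spike_frames=ph.spike_frames,
        spike_magnitude_um=ph.spike_magnitude_um,
        seed=cfg.stage_seed("phantom_motion"),
    )
    fwhm_to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    stack = phantom.render_frames(
        truth,
        ph.region_size_um,
        psf_sigma_um=tuple(f * fwhm_to_sigma for f in ph.psf_fwhm_um),
        pixel_spacing=ph.pixel_spacing_um,
        bubble_amplitude=ph.bubble_amplitude,
        background_amplitude=ph.background_amplitude,
        noise_sigma=ph.noise_sigma,
        motion_profile_um=motion,
        decorrelate_frames=ph.spike_frames,
        seed=cfg.stage_seed("phantom_render"),
    )
    return stack, truth


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, float | int] = {}

    # --- input -----------------------------------------------------------
    truth = None
    if cfg.input_stack is not None:
        stack = mio.read_frame_stack(cfg.input_stack)
    else:
        stack, truth = _build_phantom(cfg)
    if stack.n_frames > cfg.max_frames:
        stack = stack.copy_with(stack.frames[: cfg.max_frames])
    counts["n_frames"] = stack.n_frames
    mio.write_frame_stack(stack, out / "frames.tif")

    if cfg.roi_polygon is not None:
        verts = mio.read_roi_polygon(cfg.roi_polygon)
        roi = preproc.roi_mask_from_polygon(verts, stack.shape, stack.pixel_spacing)
    else:
        roi = np.ones(stack.shape, dtype=bool)

    # --- preprocessing ---------------------------------------------------
    motion = preproc.estimate_rigid_motion(stack, upsample_factor=cfg.upsample_factor)
    motion = preproc.exclude_frames(
        motion, cfg.displacement_limit_um, cfg.correlation_floor
    )
    counts["n_excluded_frames"] = int(motion.excluded.sum())
    compensated = preproc.compensate_motion(stack, motion)
    background = preproc.temporal_rank_background(
        compensated, rank=cfg.rank, half_window=cfg.half_window
    )
    fg = preproc.foreground(compensated, background)
    if cfg.threshold is not None:
        threshold = cfg.threshold
    elif stack.destruction_frame is not None:
        threshold = preproc.calibrate_threshold(
            fg, stack.destruction_frame, cfg.dead_window, roi=roi
        )
    else:
        threshold = preproc.calibrate_threshold(fg, None, roi=roi)
    counts["threshold"] = float(threshold)
    detections = preproc.detect_bubbles(
        fg, threshold, roi, min_pixels=cfg.min_pixels, motion=motion
    )
    counts["n_detections"] = len(detections)
    mio.write_detections(detections, out / "detections.csv")

    # --- tracking --------------------------------------------------------
    model = mcmcda.MotionModelParams(
        process_noise_sigma=cfg.process_noise_sigma,
        measurement_noise_sigma=cfg.measurement_noise_sigma,
        max_speed=cfg.max_speed,
        p_detect=cfg.p_detect,
        false_alarm_rate=cfg.false_alarm_rate,
        birth_rate=cfg.birth_rate,
        p_terminate=cfg.p_terminate,
        max_missed_frames=cfg.max_missed_frames,
        gate_slack_um=cfg.gate_slack_um,
    )
    assoc = mcmcda.run_mcmcda(
        detections, model, n_iterations=cfg.n_iterations, seed=cfg.stage_seed("tracking")
    )
    tracks = mcmcda.tracks_to_kinematics(assoc)
    counts["n_tracks"] = len(assoc.tracks)
    counts["n_false_alarms"] = len(assoc.false_alarms)
    mio.write_tracks(tracks, out / "tracks.csv")
    mio.write_association_summary(assoc, out / "association.json")

    # --- super-resolution maps ------------------------------------------
    extent_um = (
        stack.shape[0] * stack.pixel_spacing[0],
        stack.shape[1] * stack.pixel_spacing[1],
    )
    grid = superres.GridSpec.covering(extent_um, cfg.pixel_size_um)
    maps = superres.rasterize_tracks(tracks, grid)
    # ROI resampled onto the super-resolution grid
    rr = (np.arange(grid.shape[0]) * cfg.pixel_size_um / stack.pixel_spacing[0]).astype(int)
    cc = (np.arange(grid.shape[1]) * cfg.pixel_size_um / stack.pixel_spacing[1]).astype(int)
    rr = np.clip(rr, 0, stack.shape[0] - 1)
    cc = np.clip(cc, 0, stack.shape[1] - 1)
    maps.roi_mask = roi[np.ix_(rr, cc)]
    maps.rim_mask, maps.core_mask = superres.split_rim_core(
        maps.roi_mask, cfg.pixel_size_um, cfg.rim_thickness_um
    )
    mio.write_maps(maps, out)
    try:
        counts["resolution_fwhm_um"] = superres.estimate_resolution_fwhm(
            maps.count_map, cfg.pixel_size_um, cfg.min_passages
        )
    except ValueError:
        counts["resolution_fwhm_um"] = float("nan")

    # --- parameters ------------------------------------------------------
    pset = params.compute_parameters(
        maps,
        region=cfg.analysis_region,
        velocity_threshold_mm_s=cfg.velocity_threshold_mm_s,
        subregion_size_um=cfg.subregion_size_um,
        n_bins=cfg.entropy_bins,
    )
    pd.DataFrame([pset.as_dict()]).to_csv(out / "parameters.csv", index=False)

    # --- reference methods ----------------------------------------------
    miot = refmethods.miot_rbv(stack, roi)
    replenishment = None
    if stack.destruction_frame is not None and (
        stack.n_frames - stack.destruction_frame - cfg.dead_window
        >= 5 * stack.frame_rate
    ):
        replenishment = refmethods.fit_replenishment(
            stack,
            roi,
            destruction_frame=stack.destruction_frame,
            dead_window=cfg.dead_window,
            beam_width_mm=cfg.beam_width_mm,
        )
    ref_summary = {"miot_rbv": miot.rbv}
    if replenishment is not None:
        ref_summary.update(
            {
                "replenishment_beta_per_s": replenishment.rate_beta,
                "replenishment_velocity_proxy_mm_s": replenishment.velocity_proxy,
                "replenishment_converged": replenishment.converged,
            }
        )
    (out / "reference.json").write_text(json.dumps(ref_summary, indent=2))

    # --- manifest --------------------------------------------------------
    cfg_dict = cfg.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "paper_profile": cfg.paper_constants(),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(
        config=cfg,
        stack=stack,
        truth=truth,
        motion=motion,
        detections=detections,
        association=assoc,
        tracks=tracks,
        maps=maps,
        parameters=pset,
        miot=miot,
        replenishment=replenishment,
        manifest=manifest,
        output_dir=out,
    )
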