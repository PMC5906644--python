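"""Run configuration: one dataclass, one YAML file, one root seed.

Every tunable of the pipeline lives here with its default.  The
defaults marked "paper profile" are the constants of the published
processing chain this package implements: temporal rank filter rank 3
over ±10 frames, 5 µm super-resolution pixels, 0.5 mm rim, 25 µm
entropy sub-regions, 0.7 mm s⁻¹ velocity threshold, ≥5 passages for
the resolution estimate, at most 2000 processed frames, 50 Hz phantom
frame rate.  All per-stage randomness derives from ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "PhantomConfig"]


@dataclass
class PhantomConfig:
    region_size_um: tuple[float, float] = (2000.0, 2000.0)
    n_segments: int = 10
    radius_range_um: tuple[float, float] = (5.0, 40.0)
    speed_range_mm_s: tuple[float, float] = (0.3, 1.2)
    duration_s: float = 4.0
    frame_rate: float = 50.0  # paper profile
    bubble_rate_per_s: float = 10.0
    destruction_frame: int | None = None
    dead_window: int = 10
    lateral_dispersion: float = 0.0
    pixel_spacing_um: tuple[float, float] = (11.6, 11.6)
    psf_fwhm_um: tuple[float, float] = (40.0, 90.0)
    bubble_amplitude: float = 1.0
    background_amplitude: float = 0.0
    noise_sigma: float = 0.0
    spike_frames: tuple[int, ...] = ()
    spike_magnitude_um: float = 80.0
    jitter_sigma_um: float = 0.0


@dataclass
class RunConfig:
    """Full configuration of an end-to-end run."""

    seed: int = 0
    output_dir: str = "mulm_output"
    input_stack: str | None = None  # TIFF path; None -> phantom mode
    roi_polygon: str | None = None  # CSV/JSON path; None -> whole field

    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    # preprocessing (paper profile where marked)
    max_frames: int = 2000  # paper profile
    upsample_factor: int = 4  # paper profile
    displacement_limit_um: float = 40.0
    correlation_floor: float = 0.8
    rank: int = 3  # paper profile
    half_window: int = 10  # paper profile
    min_pixels: int = 2
    dead_window: int = 10
    threshold: float | None = None  # None -> adaptive calibration

    # tracking
    process_noise_sigma: float = 2.0
    measurement_noise_sigma: float = 2.0
    max_speed: float = 5.0
    p_detect: float = 0.9
    false_alarm_rate: float = 1.0
    birth_rate: float = 0.5
    p_terminate: float = 0.1
    max_missed_frames: int = 2
    gate_slack_um: float = 10.0
    n_iterations: int | None = None  # None -> 2000 x n_detections

    # maps and parameters
    pixel_size_um: float = 5.0  # paper profile
    rim_thickness_um: float = 500.0  # paper profile
    velocity_threshold_mm_s: float = 0.7  # paper profile
    subregion_size_um: float = 25.0  # paper profile
    entropy_bins: int = 8
    min_passages: int = 5  # paper profile
    analysis_region: str = "core"

    # reference methods
    beam_width_mm: float = 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        ph = data.pop("phantom", {})
        if isinstance(ph, dict):
            for key in ("region_size_um", "radius_range_um", "speed_range_mm_s",
                        "pixel_spacing_um", "psf_fwhm_um", "spike_frames"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            phantom = PhantomConfig(**ph)
        else:
            phantom = ph
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(phantom=phantom, **data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def paper_constants(self) -> dict:
        """The published-profile constants, for the run manifest."""
        return {
            "rank": self.rank,
            "half_window": self.half_window,
            "upsample_factor": self.upsample_factor,
            "pixel_size_um": self.pixel_size_um,
            "rim_thickness_um": self.rim_thickness_um,
            "subregion_size_um": self.subregion_size_um,
            "velocity_threshold_mm_s": self.velocity_threshold_mm_s,
            "max_frames": self.max_frames,
            "min_passages": self.min_passages,
            "frame_rate": self.phantom.frame_rate,
        }

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the root seed."""
        stages = ["phantom_network", "phantom_bubbles", "phantom_motion",
                  "phantom_render", "tracking"]
        return (int(self.seed) * 97 + stages.index(stage) + 1) % (2**31 - 1)
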