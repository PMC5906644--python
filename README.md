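# mulm — motion-model ultrasound localization microscopy

`mulm` reconstructs super-resolution maps of tumor vasculature from
ordinary contrast-enhanced ultrasound (CEUS) cine loops and quantifies
the vascular phenotype with a set of morphological and functional
parameters.  It targets the regime of clinical scanners and clinically
recommended microbubble doses: ~50 frames per second, tens of bubbles
per frame, and appreciable tissue motion — conditions under which
naive nearest-neighbor bubble tracking fails.

It is written for researchers analyzing preclinical or clinical CEUS
loops of tumors who want vessel-scale readouts (relative blood volume,
inter-vessel distances, flow speeds and directions) instead of
voxel-scale intensity statistics, plus a fully synthetic phantom so
every stage can be validated against known ground truth.

## Method

**Detection.** Frames are rigidly registered to a reference by
upsampled phase cross-correlation (4-fold sub-pixel grid); frames with
large displacements or strong decorrelation — breathing spikes with
out-of-plane motion — are excluded.  The static tissue background is a
per-pixel temporal rank filter (rank 3 over ±10 frames) and is
subtracted; the detection threshold is calibrated so that the frames
immediately after a destructive pulse, which contain no bubbles, yield
zero detections.  Each supra-threshold blob is localized at its
intensity-weighted centroid, sub-pixel.

**Tracking.** Detections are grouped into trajectories by Markov Chain
Monte Carlo Data Association (MCMCDA).  An association ω is a
partition of all detected positions Y into tracks and false alarms,
scored by the posterior

    P(ω | Y) ∝ P(Y | ω) · P(ω)

where P(Y | ω) is the Kalman-filter innovation likelihood of each
track under a constant-velocity (linear) motion model, and P(ω) is a
structural prior built from Poisson track births and false alarms,
geometric track survival, and binomial detection/miss probabilities.
A Metropolis–Hastings chain explores association space with
birth/death, extend/reduce, split/merge, tail-switch, insert and
update moves; the highest-posterior association visited is kept.  On
tiny instances the sampler is verified against exhaustive enumeration
of every valid association.

**Maps and parameters.** Accepted tracks are drawn with Bresenham
lines onto a 5 µm grid, producing binary track, flow-velocity,
flow-direction and passage-count maps.  The tumor ROI splits into a
0.5 mm rim and a core (the core carries the analysis, excluding large
feeding vessels).  Per region the package computes rBV (track-covered
area fraction), mean/variance/maximum/median of the Euclidean distance
to the closest vessel (distance transform), the same statistics of the
flow speeds, those distance statistics stratified by slow vs fast flow
(threshold 0.7 mm s⁻¹), and the local flow-direction entropy over
25 µm sub-regions.  The achieved resolution is estimated from the
full-width-half-maximum of vessels crossed by at least five bubbles.

**Reference analyses and cohort statistics.** For comparison the
package implements Maximum Intensity Over Time (MIOT) rBV and
destruction–replenishment velocity estimation (Wei model
A·(1 − e^(−βt))), plus cohort-level one-way ANOVA with Bonferroni
post-hoc tests, nearest-neighbor leave-one-out classification with
confusion matrices, and Pearson correlation matrices of parameters.

## Worked example

A fully synthetic run: 8 random vessels, 3 s at 50 Hz, zero noise,
tracked and quantified end-to-end.

```python
from mulm import RunConfig, PhantomConfig, run_pipeline

cfg = RunConfig(
    seed=1,
    output_dir="example_out",
    phantom=PhantomConfig(
        region_size_um=(2000.0, 2000.0), n_segments=8, duration_s=3.0,
        bubble_rate_per_s=10.0, background_amplitude=0.3,
    ),
    threshold=0.15,
    n_iterations=150_000,
)
res = run_pipeline(cfg)
print("detections       :", res.manifest["counts"]["n_detections"])
print("tracks           :", res.manifest["counts"]["n_tracks"])
p = res.parameters
print(f"core rBV         : {p.rbv:.4f}")
print(f"dist mean/max    : {p.dist_mean:.1f} / {p.dist_max:.1f} um")
print(f"velocity mean    : {p.vel_mean:.3f} mm/s (median {p.vel_median:.3f})")
print(f"direction entropy: {p.direction_entropy:.3f} bits")
```

prints

```
detections       : 1316
tracks           : 85
core rBV         : 0.0103
dist mean/max    : 309.9 / 996.2 um
velocity mean    : 0.781 mm/s (median 0.805)
direction entropy: 0.080 bits
```

1316 bubble echoes were grouped into 85 trajectories; the rasterized
vessels cover ~1 % of the core; the farthest core pixel is ~1 mm from
a vessel (a large unperfused pocket); mean bubble speed is
0.78 mm s⁻¹; the low entropy reflects the locally straight designed
flow.  The output directory holds the detections and tracks as CSV,
the maps as 32-bit TIFF, the parameter row as CSV, and a manifest with
the configuration and per-stage counts.

The same pipeline runs from the shell:

```bash
mulm run --config config.yaml --seed 1 --output example_out
mulm show-config          # all defaults, including the standard profile
```

For real data, set `input_stack` to a multi-page TIFF with a JSON
sidecar (frame rate, pixel spacing, optional destruction frame) and
`roi_polygon` to a CSV/JSON vertex list of the tumor outline.

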