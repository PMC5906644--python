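# Methods

This note documents the models, parameter choices and numerical
decisions behind `mulm`, and what the synthetic phantom does and does
not establish about real data.

## Processing model

### Motion estimation and frame exclusion

Rigid in-plane translation per frame is estimated by phase
cross-correlation against a single reference frame (the first frame),
on a 4-fold upsampled grid, so displacements are resolved to a quarter
pixel (2.9 µm at the default 11.6 µm pitch).  The similarity of each
registered frame with the reference is recorded as a Pearson
correlation.  Frames are excluded outright when their displacement
magnitude exceeds `displacement_limit_um` (default 40 µm) **or** their
correlation falls below `correlation_floor` (default 0.8): large
displacement spikes from breathing are accompanied by decorrelation
indicating out-of-plane motion that no in-plane shift can correct.
The two cut-offs are configuration values, not measured constants; the
defaults sit between the typical retained-frame displacements
(~10–21 µm) and the spike regime (≳60 µm) of small-animal scans.
Compensation translates retained frames by the negated displacement
with cubic-spline interpolation; excluded frames are passed through
untouched and skipped downstream, so frame indices stay stable.

### Background separation and detection

The background estimate at pixel p, frame t is the rank-3 (3rd
smallest) value of p over frames t ± 10.  The window truncates at the
sequence ends and the rank is clamped to the truncated window length.
Rank from the *bottom* of the sorted window is used because transient
bright bubbles must not leak into the background; a low rank still
tolerates a couple of dark outliers.  Foreground is the clipped
difference.  The detection threshold is, when a destruction event is
recorded, the smallest value for which the bubble-free dead-window
frames yield zero detections (the maximum dead-window foreground, plus
one ulp); without a destruction event a 99.9th-percentile fallback
over early frames is used and a warning logged — this is a heuristic,
not a calibration.  Detections are 8-connected supra-threshold
components of at least `min_pixels` (default 2, rejecting single-pixel
noise) localized at the intensity-weighted centroid; components
touching the ROI boundary are kept.

### Track association

The tracker operates in µm and frame units internally.  The state of
a track is position and velocity per axis; the transition over a gap
of n frames uses the discrete white-acceleration model with
per-axis process noise covariance
`q² · [[n⁴/4, n³/2], [n³/2, n²]]`, `q = process_noise_sigma`
(µm per frame², default 2).  Measurement noise is isotropic with
std `measurement_noise_sigma` (default 2 µm, the scale of centroid
error at moderate SNR).  A track's first detection is scored uniform
over the ROI area, exactly like a false alarm, so the likelihood
comparison between "track" and "clutter" hypotheses is fair; the
velocity is initialized diffusely with std `max_speed` so the second
detection is only weakly informative and the model "locks on" from the
third detection.

The structural prior factorizes per frame: Poisson counts for track
births (`birth_rate`, default 0.5/frame) and false alarms
(`false_alarm_rate`, default 1/frame), geometric survival
(`p_terminate`, default 0.1) charged for every frame a track spans
after its first, binomial detection (`p_detect`, default 0.9) with
misses charged for skipped interior frames, and a termination factor
for tracks ending before the last frame.  All constants are exposed in
`MotionModelParams`; none is claimed to be a measured value.

Candidate links are gated: a link spanning g frames is admissible iff
its implied speed ≤ `max_speed` (default 5 mm s⁻¹, an order above
typical tumor flow) within an additive slack of `gate_slack_um`
(default 10 µm, absorbing localization noise), and g ≤
`max_missed_frames` + 1 (default 2 missed frames).  The
Metropolis–Hastings chain starts from the all-false-alarm association
and uses nine moves: birth (grow a gated chain from a random free
detection), death, extend, reduce, split, merge, tail switch, update
(same-frame swap or interior removal) and insert (fill an interior
missed frame).  The birth/death pair carries an explicit
proposal-probability correction; the remaining moves are treated as
symmetric, an approximation that biases the *stationary distribution*
slightly but not the reported result, which is the highest-posterior
association visited (the chain is used as a guided stochastic search
for the MAP, and the MAP report is verified against exhaustive
enumeration on tiny instances).  The default budget is 2000 moves per
detection.  Ties are broken toward fewer tracks, then lexicographic
track order, so results are reproducible bit-for-bit given a seed.

`exhaustive_map` enumerates every valid partition (processing
detections in frame order; each may join a gated open track, start a
track, or be clutter) and is guarded to ≤ 10 detections; it exists
solely as the exact oracle.

### Maps, regions and parameters

Tracks are rasterized at `pixel_size_um` = 5 µm (≈ λ/8, an eighth of
the 40 µm axial point-spread extent).  Bresenham lines connect
consecutive detections *including* across permitted missed-frame gaps
— a track is a single trajectory regardless of how many frames a
detection was missed for; this is configurable at the call site by
splitting tracks beforehand.  A pixel crossed by several segments of
one track counts as **one** passage; pixels shared by several tracks
accumulate one passage each and keep the passage-weighted mean speed
and the circular (vector) mean direction, stored in (−π, π] measured
from the +lateral axis toward +axial.  Count-weighted arithmetic means
are an unbiased summary absent any stated alternative; the circular
mean avoids the wrap-around artifact of averaging angles.

The rim is every ROI pixel within 0.5 mm (Euclidean distance
transform) of the ROI boundary; the core is the rest, and is the
default analysis region because large feeding vessels concentrate in
the rim.  Distance maps use the exact Euclidean distance transform on
the full grid (the nearest vessel to a region pixel may lie outside
the region).  All four-statistics use the population variance
(ddof = 0): the pixel set is the complete population of the region,
not a sample.  Velocity stratification at 0.7 mm s⁻¹ splits strictly:
slow < threshold ≤ fast; a cohort-derived threshold (mean of per-tumor
median velocities) is available via `cohort_velocity_threshold`.
Flow-direction entropy tiles the region into 25 µm sub-regions (5×5
grid pixels), histograms on-track directions into 8 equal angular bins
(45°; the bin count is a package choice, exposed as `n_bins`),
computes base-2 Shannon entropy per tile, and averages over tiles that
contain at least one track pixel — empty tiles are excluded rather
than counted as zero, since they carry no direction information.  The
histogram is per-pixel and unweighted by passage count.

The resolution protocol considers only pixels with ≥ 5 passages (a
vessel sampled once is one pixel wide by construction and says nothing
about resolution).  For each qualifying local maximum, row and column
cross-profiles of the count map are measured at half maximum with
linear interpolation; the smaller of the two widths is the
cross-section (the larger runs along the vessel), and the minimum over
all qualifying profiles is reported.

### Reference analyses

MIOT: per-pixel temporal maximum minus per-pixel temporal median,
Otsu-segmented within the ROI (override available); rBV = segmented
fraction.  Replenishment: mean ROI intensity from the end of the
destruction dead window, baseline-subtracted, fitted to
A·(1 − e^(−βt)) by bounded least squares with data-driven starting
values; non-convergence or a fit explaining less than half the plateau
is *reported* (`converged=False`), never raised, since noisy clinical
replenishment curves often cannot be fitted.  The velocity proxy is
β × `beam_width_mm` (default 1 mm); this conversion ignores the beam
elevation profile and is known to be inaccurate — only β recovery is
asserted quantitatively, the proxy appears only in ordering checks.

### Cohort statistics

Post-hoc pairwise comparisons use t statistics with the pooled
within-group variance of all groups (df = N − k), each p multiplied by
the number of pairs and capped at 1 (classical Bonferroni post-hoc).
Brown–Forsythe and Shapiro–Wilk checks are computed as advisory
numbers only and never gate the ANOVA.  The NN-LOOCV classifier
z-scores the feature columns over the cohort before computing
Euclidean distances (for the single-parameter classifications this is
order-preserving and changes nothing); distance ties break toward the
smallest tumor index, making the confusion matrix independent of row
order.

## The phantom

The generator emulates exactly the features the pipeline keys on:
sparse anisotropic-Gaussian point echoes (default FWHM 40 µm axial ×
90 µm lateral, the focal point-spread scale of a small-animal
scanner) advected along straight vessel segments at plug-flow speed;
a static low-pass speckle background; additive Gaussian sensor noise;
whole-frame rigid motion with optional breathing-like spikes plus
multiplicative decorrelation on spike frames; and an optional
destruction–replenishment event (all bubbles killed, a dead window
with no births).  Bubble in-plane persistence has no canonical value
and is exposed as two knobs: entry mode (at the segment start, for
transit-limited replenishment phantoms, or uniform along the vessel,
as bubbles drifting into the elevational slice) and a dwell cap that
produces the few-to-ten-detection tracks typical of in vivo loops.
Bubbles ride the vessel centreline by default (`lateral_dispersion=0`)
so designed phantoms have exact one-pixel rasterized widths; a
dispersion fraction of the lumen radius is available.

Deliberately not modelled: acoustic propagation, nonlinear bubble
oscillation, attenuation, speckle decorrelation from deformation,
non-rigid motion, and any elevational geometry.  Consequently the
validation experiments establish the *correctness* of the chain
(localization, association, geometry, statistics) under the stated
model, not its robustness to the full physics of in vivo imaging; the
absolute in vivo parameter values of real tumor cohorts are outside
what a synthetic phantom can reproduce.

### Designed experiment sizes

The built-in experiments are sized for a single CPU: ten parallel
vessels at 0.3–1.2 mm s⁻¹ with five full-transit bubbles each (~840
detections, ~220 frames) for recovery; 50 random ≤10-detection
instances against exhaustive enumeration (sampler budget 80 000 moves,
where the hardest observed instance needs the chain to cross a
posterior valley); four 3.6 mm vessels at 0.3–0.6 mm s⁻¹ for the
reference-method comparison, whose transit times of 6–12 s make the
replenishment refill transit-limited as tumor perfusion is in vivo;
100 curves for the replenishment-recovery experiment; 100 random
50×50 grids for the distance-transform check.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` from
  explicit seeds; the pipeline splits one root seed per stage.
- Threshold comparison is strict (`foreground > threshold`); the
  calibrated threshold is one ulp above the dead-window maximum.
- Rank filter windows shorter than the rank clamp the rank; sequences
  shorter than the rank are rejected.
- A blank (zero-variance) frame has undefined correlation and is
  excluded at motion estimation.
- An empty detection set yields the empty association; an empty
  velocity stratum yields NaN stratified statistics, flagged rather
  than raised; a ROI thinner than twice the rim yields an empty core
  with a warning and the analysis proceeds on the rim only if asked.
- Track-score caching keys on the detection-index tuple; incremental
  chain scoring accumulates float error below 1e-9 over typical runs,
  and the returned association is always re-scored exactly.

## Known limitations

- The sampler's non-birth/death moves assume proposal symmetry; the
  sampled distribution is therefore only approximately the posterior.
  Only the MAP-over-visited is reported or tested.
- Bresenham rasterization quantizes sub-pixel track positions to the
  5 µm grid; widths below one grid pixel are not representable.
- The replenishment velocity proxy shares the known inaccuracy of
  beam-width-based conversions; treat it as a relative, not absolute,
  readout.
- 2-D only: all distances, speeds and directions are in-plane.
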