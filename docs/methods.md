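# Methods

## Scope and data model

`flashtrace` measures flash signaling and flight behavior of point-like
bioluminescent sources in fixed-camera, constant-frame-rate video. The
pipeline's objects mirror the measurement chain:

* **FrameSequence** — an (n, h, w) stack of single-channel frames in raw
  sensor units with a frame rate; the timestamp of frame *i* is
  `t0 + i / frame_rate`. Color input is collapsed to luminance with
  Rec. 601 weights at load. Coordinates are 0-based, origin top-left,
  x rightward, y downward, pixel centers on integers.
* **Track** — one individual's circular ROI per frame over a contiguous
  frame range. A pixel belongs to the ROI iff its Euclidean distance to
  the center is ≤ radius. Tracks may superpose; when two centers come
  within one radius a warning is logged, because the two individuals'
  light is then not separable.
* **IntensityTrace** — the background-corrected ROI intensity versus time;
  the substrate of all pattern metrics.

## Photometry

The intensity at frame *i* is the **sum** of (pixel − background) over the
ROI, with the net value clipped at zero. Summing (rather than averaging)
makes the value the source's total excess flux, insensitive to the ROI
radius once the point-spread function is enclosed; a `mean` aggregator is
available. Background is the median of the annulus between radius and
2×radius around the ROI center, excluding pixels inside any other track's
ROI (so a neighbor's flash cannot inflate the background) and falling back
to the whole-frame median when clipping/exclusion empties the annulus.
Median-of-annulus cancels any spatially uniform background exactly, which
the tests assert. Photometry always reads raw frames; display gain/offset
adjustments are render-only.

## Tracking

Automated tracking is deliberately simple: connected components of pixels
above a user threshold (centroid = brightness-weighted mean, deterministic
ordering by descending total brightness) linked frame-to-frame by greedy
nearest-neighbor assignment in order of increasing distance. Ties at equal
distance resolve to the lower track id; a detection farther than
`max_jump` from every live track starts a new track; a track unmatched for
more than `max_gap` frames is closed; interior unmatched frames become
gaps with linearly interpolated centers (keeping traces aligned to the
frame clock); tracks with fewer than `min_obs` detections are dropped as
noise blips. On well-separated targets (inter-spot distance more than
twice the per-frame displacement) greedy linking provably coincides with
minimum-total-displacement matching, and the tests verify this against an
exhaustive-permutation oracle. There is no identity re-acquisition after
long occlusion and no crossing resolution — coinciding paths stay
superposed, as in manual tracing.

Flashing sources vanish between flashes, so an automatically found track
begins at its first detection and ends at its last; the first and last
flash of such a track would be truncated and bias duration estimates. The
pipeline therefore (optionally, default on for auto mode) *extends* each
track over the whole sequence holding the boundary centers fixed, and the
segmenter can drop events whose onset/offset touches the trace boundary.
Both behaviors are plumbing choices of this implementation, configurable
via `extend_tracks` and `drop_partial`.

### Parameter guidance

| parameter | unit | default | role |
| --- | --- | --- | --- |
| `threshold` | sensor units | 10 | detection level; set ≳ background + 5·noise σ |
| `max_jump` | px/frame | 12 | gate for frame-to-frame association |
| `max_gap` | frames | 2 | frames a track survives undetected; raise to ≥ the longest dark gap × frame rate when tracking flashers |
| `min_obs` | detections | 3 | discard shorter tracks |
| `roi_radius` | px | 6 | ≥ 4×PSF σ captures >99.9% of a Gaussian source |

## Flash segmentation and metrics

The baseline is the 10th-percentile trace value (robust to isolated dark
samples). Segmentation is two-pass: a coarse pass thresholds at
`onset_frac` (default 0.1) of the global peak above baseline to locate
candidate segments; each segment is then re-thresholded against its own
peak, so flashes of unequal amplitude are bounded consistently. Onset and
offset are placed by linear interpolation between samples, giving
sub-frame boundaries. Segments separated by a dark gap shorter than
`merge_gap` (default 0.3 s) merge into one multi-pulse flash — this is how
a "twinkling" flash is resolved into a bimodal double-pulsed one. Peaks
are local maxima with prominence ≥ `min_prominence_frac` × (max − min) of
the trace; plateau maxima (rectangular flashes) report the plateau center.

Conventions (all configurable):

* **flash duration** — onset to offset at 10% of peak-above-baseline.
  Half-maximum analysis is `onset_frac = 0.5`. Ten percent approximates
  the visible start of a flash better than half-max for asymmetric
  envelopes.
* **peak interval** — first peak of one flash to first peak of the next.
* **interflash interval** — the dark gap (offset → next onset), not
  peak-to-peak; the peak-based rhythm is already reported as the peak
  interval.
* **sub-pulse interval** — successive peaks within one flash, pooled over
  flashes.

All time metrics are invariant to amplitude rescaling and equivariant
under time shifts, which the property tests check. Segmentation recovers
simulator truth within one frame period at 30 fps for rectangular,
raised-cosine and double-pulsed envelopes over ≥20 flashes.

## Signal analyses

* **Synchrony** — Pearson correlation of two traces at every integer-frame
  lag within ±`max_lag`, each lag over the overlapping window only,
  mean-removed and unit-variance normalized. The best lag is the argmax
  (smallest |lag| on ties). Groups larger than two are summarized by the
  mean pairwise zero-lag correlation. Correlations are computed on raw
  traces by default; a binarized (0/1 flash train) variant is available.
* **Spectrum** — one-sided periodogram of the mean-removed trace (boxcar
  window by default; any scipy window can be requested as a taper),
  density scaling, so the integrated power equals the trace variance
  (Parseval, asserted to within 1%).
* **Fractal dimension** — box counting on the flight path. The polyline is
  densified to ≤0.5 px sample spacing so sparse frame sampling cannot
  starve small boxes; grids are anchored at the bounding-box corner (no
  anchor averaging, for determinism) with dyadic box sizes from the larger
  bounding-box dimension down `n_scales` halvings (smallest box ≥ 2 px);
  the dimension is the least-squares slope of log N vs log (1/s), with the
  fit's R² reported. A straight line measures ≈1, a filled square ≈2, and
  the estimate is invariant under rigid translation (exactly) and uniform
  scaling (within fit tolerance).

## Rendering

The orbit-line figure draws the flight path polyline with a circle at each
sample whose radius encodes the intensity quantized into `n_steps`
(default 7) ordinal levels — equal-width bins over the observed range
(half-open, closed at the top: the maximum maps to the top step, a
constant trace to step 1), with an equal-quantile option. Circle radii
default to 2 px + 2 px per step; step-1 circles can be suppressed to
de-clutter dark phases (default off). The time-course graph plots each
trace in the fixed palette red, brown, green, purple, blue (cycling), with
an optional red vertical cursor at a chosen frame. The overlay video
burns ROI circles (dashed at interpolated-gap frames), trailing path
polylines, and an optional seconds.milliseconds timer into each frame,
preserving frame count, size and rate.

## Synthetic scenes

The simulator renders each individual as an isotropic Gaussian
(pixel-integrated via the error function, so total image flux equals the
envelope flux to numerical precision) whose integrated brightness follows
a periodic flash envelope, over a uniform background with optional
Gaussian read noise and Poisson shot noise. Trajectories (stationary,
linear, random-walk, sinusoidal weave) reflect at the frame borders so
sources stay in view. Identical scene specifications, including the seed,
render bit-identical frames.

Envelope models:

* **rectangular** — constant flux over the flash window; with
  `n_subpulses > 1`, disjoint short pulses (`subpulse_width` each, peaks
  `subpulse_interval` apart), for rapid multi-flash bursts. Duration truth
  is the envelope support.
* **raised_cosine** — a smooth hump whose width is solved so the envelope's
  width at 10% of peak equals `flash_duration`, matching the segmenter's
  onset convention. With `n_subpulses > 1` the envelope is a carrier hump
  (60% of amplitude) plus narrow sub-pulse bumps (40%, width 0.7×interval)
  spaced `subpulse_interval` apart — a sustained glow carrying closely
  spaced peaks whose trough stays well above baseline, i.e. a twinkling
  flash. The carrier width is found by bisection so the composite
  10%-width still equals `flash_duration`.

Truth metrics (duration, peak times, sub-pulse interval) are measured
numerically on the continuous envelope at 0.5 ms resolution with the same
10% convention the segmenter uses, so truth and recovery share one
operational definition; the truth sub-pulse spacing of the twinkle model
(e.g. 137 ms for nominal 140 ms bumps) reflects the real peak positions of
the composite envelope, and recovery is compared against that.

Two presets encode the demonstration conditions: `cruciata_like` (five
flying individuals, single-peak 1.3 s flashes every 1.9 s, per-individual
phase jitter of σ = 0.12 s giving loosely synchronous group flashing;
20 s at 30 fps, 120×160 px) and `lateralis_pair` (a near-stationary pair:
male-analog with bimodal 0.566 s flashes, 0.14 s sub-pulse spacing and
0.624 s dark gaps; female-analog with rapid triple flashes; 16 s at
30 fps, 96×128 px). Both use PSF σ = 1.2 px, background 2, read noise
σ = 1 sensor unit — a high-SNR but quantization-limited regime typical of
intensified night recordings. These sizes keep a full pipeline run on one
CPU in a few seconds while providing ≥10 flashes per individual.

What the simulator does **not** emulate: vegetation occlusion, camera
motion, vignetting or flat-field structure, motion blur within a frame,
compression artifacts, and optically crossing individuals. Passing
recovery tests therefore demonstrate the correctness of the measurement
chain under clean conditions, not robustness to every field artifact.

## Numerical choices and degenerate inputs

* Constant traces: no peaks, no events, quantization maps wholly to step 1.
* Zero-variance traces make correlation undefined → explicit error.
* A fit slope marginally above 2 from round-off is clamped to the planar
  bound 2.0.
* Box-grid boundary points are folded into the last cell of their
  row/column so the bounding-box edge does not create phantom boxes.
* Uint8 video export rounds (not truncates) pixel values; truncation
  would bias the noise floor by half a unit, which is material when the
  background is only a few counts.
* CSV exports write full-precision floats; exact re-parsing requires
  pandas' `float_precision="round_trip"` reader, as used in the tests.

## Known limitations

* Uncompressed DIB is the only AVI codec supported natively; compressed
  recordings must be transcoded or exported as TIFF frame stacks first.
* Greedy linking will mis-assign identities when targets approach within
  one frame's travel of each other; such scenes should be traced manually
  (the manual-trace CSV dialect exists for exactly this).
* Background estimation assumes a locally uniform background; strong
  gradients within 2×radius of a source will bias the trace.
* The seven-step "optimal" allocation of intensity circles is a
  convention (equal-width or equal-quantile), not an optimization.
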