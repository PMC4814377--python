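# flashtrace

Flash-signal photometry and flight-path analysis of bioluminescent
organisms from time-lapse video.

Fireflies (and many other bioluminescent animals) communicate with
species-specific flash patterns: the duration of each flash, the rhythm of
successive flashes, and fine sub-pulse structure inside a single flash all
carry signal. Quantifying these patterns from night video traditionally
means tracing each individual frame by frame on a monitor and reading off a
region-of-interest (ROI) brightness value. `flashtrace` is a scriptable
library + CLI that automates that workflow end to end:

1. **video_io** — load AVI files or numbered TIFF/PNG frame stacks, trim
   scenes, export frames, apply non-destructive display adjustments;
2. **tracking** — one circular ROI per individual per frame, from a manual
   trace CSV or from automated spot detection with greedy nearest-neighbor
   linking;
3. **photometry** — background-corrected ROI intensity *I_i(t)* = Σ_ROI
   (pixel − median annulus background), one trace per individual;
4. **flash_metrics** — segment each trace into flash events at a threshold
   fraction of peak-above-baseline (default 10%), merging segments whose
   dark gap is shorter than `merge_gap`; report flash duration, peak
   interval, interflash interval, sub-pulse interval and pulses-per-flash;
5. **pattern_analysis** — pairwise lagged Pearson correlation (flash
   synchrony), one-sided periodogram (flash rhythm), and box-counting
   fractal dimension of flight paths (slope of log N(s) vs log 1/s);
6. **render_export** — orbit-line path figures with intensity circles
   quantized to seven ordinal steps, multi-track time-course graphs with a
   frame cursor, overlay video with burned-in ROIs, and full CSV/JSON
   export;
7. **synthetic** — a ground-truthed scene simulator (moving Gaussian point
   sources driven by parameterized flash envelopes plus sensor noise) so
   every stage is testable against known answers.

## Worked example

Simulate a courting pair — a near-stationary "male" emitting a bimodal
double-pulsed flash (0.566 s long, sub-pulse peaks 0.14 s apart, 0.624 s
dark gap) and a "female" answering with rapid triple flashes — then run the
automated pipeline on the rendered frames:

```python
import flashtrace as ft
from flashtrace.cli import RunConfig, analyze_sequence

spec = ft.preset("lateralis_pair", seed=1)
seq, truth = ft.make_scene(spec)

cfg = RunConfig(input=".", auto=True, threshold=8.0,
                max_jump=12, max_gap=45, min_obs=5, roi_radius=6.0)
stage = analyze_sequence(seq, cfg)
for tid, s in stage["summaries"].items():
    print(f"track {tid}: {s.n_flashes} flashes, "
          f"duration {s.mean_duration:.3f} s, "
          f"interflash {s.mean_interflash_interval:.3f} s, "
          f"sub-pulse {s.mean_subpulse_interval:.3f} s, "
          f"pulses/flash {sorted(set(s.pulses_per_flash))}")
```

prints

```
track 0: 13 flashes, duration 0.567 s, interflash 0.623 s, sub-pulse 0.138 s, pulses/flash [2]
track 1: 10 flashes, duration 0.328 s, interflash 1.173 s, sub-pulse 0.118 s, pulses/flash [3]
```

Track 0 is the male-analog: every flash resolved as 2-pulsed, with
duration, interflash interval and sub-pulse interval each recovered within
one frame period (1/30 s) of the simulated truth. Track 1 is the
female-analog's triple flash.

The same pipeline runs from the shell:

```sh
flashtrace simulate --preset lateralis_pair -o scene.avi --seed 1
flashtrace run -c config.yaml            # one-shot: track→measure→analyze→export
flashtrace extract-frames scene.avi frames/
flashtrace track scene.avi tracks.csv --threshold 8
flashtrace measure scene.avi tracks.csv traces.csv
flashtrace analyze traces.csv out/
flashtrace render traces.csv out/
```

`run` writes `tracks.csv`, `traces.csv`, `events.csv`, `summary.csv`,
`synchrony.csv`, `spectrum.csv`, `path_metrics.csv`, per-track orbit-line
path PNGs, the group time-course PNG, an overlay AVI, and a
`manifest.json` recording every output and parameter.

## Documentation

See `docs/methods.md` for the measurement conventions (onset/offset
thresholds, interval definitions), the synthetic scene model, numerical
choices, and known limitations.
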