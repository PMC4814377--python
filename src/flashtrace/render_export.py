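"""Graphical and text outputs: orbit-line path figures, time-course graphs,
overlay video, and the CSV/JSON export bundle.

The path figure draws the flight path as a polyline ("orbit line") with the
instantaneous light intensity shown as a circle whose size is allocated over
a small number of ordinal steps (seven by default); the time-course graph
plots every individual's trace in the fixed palette red, brown, green,
purple, blue, with an optional vertical cursor marking one frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage import draw as skdraw

from . import flash_metrics as fm
from . import photometry as phot
from . import tracking as trk
from . import video_io
from .photometry import IntensityTrace
from .tracking import Track
from .video_io import FrameSequence

__all__ = [
    "StepScale",
    "quantize_intensity",
    "render_path",
    "render_timecourse",
    "write_overlay_video",
    "export_bundle",
    "PALETTE",
]

#: Series colors for multi-individual time-course plots, in order.
PALETTE = ("red", "brown", "green", "purple", "blue")

_RGB_PALETTE = (
    (255, 60, 60), (160, 90, 40), (60, 200, 60), (170, 60, 200), (70, 110, 255)
)


@dataclass(frozen=True)
class StepScale:
    """Ordinal intensity→circle-radius scale for path rendering."""

    n_steps: int
    edges: np.ndarray  # interior bin boundaries, ascending (n_steps − 1)
    radii: np.ndarray  # circle radius per step, strictly increasing

    def __post_init__(self):
        if self.n_steps < 2:
            raise ValueError("n_steps must be ≥ 2")
        edges = np.asarray(self.edges, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if len(edges) != self.n_steps - 1:
            raise ValueError("need n_steps − 1 interior edges")
        if np.any(np.diff(edges) < 0):
            raise ValueError("edges must ascend")
        if len(radii) != self.n_steps or np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be strictly increasing, one per step")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "radii", radii)

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        n_steps: int = 7,
        radius_min: float = 2.0,
        radius_increment: float = 2.0,
        mode: str = "width",
    ) -> "StepScale":
        """Build a scale over the observed range.

        ``mode="width"`` uses equal-width bins (default); ``"quantile"``
        allocates equal-count bins instead.
        """
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("empty intensity series")
        if mode == "width":
            lo, hi = values.min(), values.max()
            edges = lo + (hi - lo) * np.arange(1, n_steps) / n_steps
        elif mode == "quantile":
            edges = np.quantile(values, np.arange(1, n_steps) / n_steps)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        radii = radius_min + radius_increment * np.arange(n_steps)
        return cls(n_steps, edges, radii)

    def step_of(self, values: np.ndarray) -> np.ndarray:
        """Map values to steps 1..n_steps (bins half-open, closed at the top)."""
        return np.searchsorted(self.edges, np.asarray(values, dtype=float), side="left") + 1


def quantize_intensity(values: np.ndarray, n_steps: int = 7) -> np.ndarray:
    """Equal-width quantization of a series into steps 1..n_steps.

    Bins are half-open, closed at the top: the minimum maps to step 1, the
    maximum to step n_steps; a constant series maps wholly to step 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty intensity series")
    if n_steps < 2:
        raise ValueError("n_steps must be ≥ 2")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=int)
    steps = np.ceil((values - lo) * n_steps / (hi - lo) - 1e-9).astype(int)
    return np.clip(steps, 1, n_steps)


def render_path(
    track: Track,
    trace: IntensityTrace,
    scale: StepScale | None = None,
    canvas: tuple[int, int] | None = None,
    suppress_min_step: bool = False,
) -> np.ndarray:
    """Raster of the orbit line with an intensity circle at each sample.

    The polyline through consecutive ROI centers is drawn at value 128, the
    intensity circles (filled disks, radius per quantization step) at 255.
    ``suppress_min_step`` omits circles for step-1 (dark-phase) samples.
    """
    if len(track) != len(trace):
        raise ValueError(
            f"track ({len(track)} frames) and trace ({len(trace)}) are misaligned"
        )
    pos = track.positions
    if scale is None:
        scale = StepScale.from_values(trace.values)
    if canvas is None:
        r = scale.radii[-1] + 2
        canvas = (
            int(np.ceil(pos[:, 1].max() + r)) + 1,
            int(np.ceil(pos[:, 0].max() + r)) + 1,
        )
    img = np.zeros(canvas, dtype=np.uint8)
    pts = np.rint(pos).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = skdraw.line(y0, x0, y1, x1)
        ok = (rr >= 0) & (rr < canvas[0]) & (cc >= 0) & (cc < canvas[1])
        img[rr[ok], cc[ok]] = np.maximum(img[rr[ok], cc[ok]], 128)
    steps = scale.step_of(trace.values)
    for (x, y), s in zip(pos, steps):
        if suppress_min_step and s == 1:
            continue
        rr, cc = skdraw.disk((y, x), scale.radii[s - 1], shape=canvas)
        img[rr, cc] = 255
    return img


def render_timecourse(
    traces: list[IntensityTrace],
    cursor_frame: int | None = None,
    out: str | Path | None = None,
    dpi: int = 100,
) -> np.ndarray:
    """Multi-track intensity graph on a shared time axis; returns an RGB raster.

    One colored series per trace in palette order (red, brown, green,
    purple, blue, cycling); the optional red vertical cursor marks the
    time of ``cursor_frame``.
    """
    if not traces:
        raise ValueError("need at least one trace")
    fig, ax = plt.subplots(figsize=(8, 3.2), dpi=dpi)
    for i, trace in enumerate(traces):
        ax.plot(
            trace.times,
            trace.values,
            color=PALETTE[i % len(PALETTE)],
            linewidth=1.0,
            label=str(trace.track_id),
        )
    if cursor_frame is not None:
        ref = traces[0]
        t = ref.times[0] + (cursor_frame - ref.frames[0]) / ref.frame_rate
        ax.axvline(t, color="red", linewidth=1.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("light intensity (sensor units)")
    ax.legend(loc="upper right", fontsize=7, title="ROI")
    fig.tight_layout()
    fig.canvas.draw()
    rgba = np.asarray(fig.canvas.buffer_rgba())
    if out is not None:
        fig.savefig(out, dpi=dpi)
    plt.close(fig)
    return rgba[..., :3].copy()


_DIGITS = {  # 3×5 bitmap glyphs for the timer stamp
    "0": "111101101101111", "1": "010110010010111", "2": "111001111100111",
    "3": "111001111001111", "4": "101101111001001", "5": "111100111001111",
    "6": "111100111101111", "7": "111001001001001", "8": "111101111101111",
    "9": "111101111001111", ".": "000000000000010", ":": "000010000010000",
}


def _stamp_text(img: np.ndarray, text: str, y: int = 2, x: int = 2) -> None:
    for ch in text:
        glyph = _DIGITS.get(ch)
        if glyph is None:
            x += 4
            continue
        bits = np.array([int(b) for b in glyph]).reshape(5, 3)
        h, w = img.shape[:2]
        ys, xs = np.nonzero(bits)
        ys, xs = ys + y, xs + x
        ok = (ys < h) & (xs < w)
        img[ys[ok], xs[ok]] = 255
        x += 4


def write_overlay_video(
    seq: FrameSequence,
    tracks: list[Track],
    traces: list[IntensityTrace] | None = None,
    out: str | Path = "overlay.avi",
    timer_stamp: bool = True,
    trail: int = 60,
) -> Path:
    """Re-encode the sequence with ROI circles and trailing paths burned in.

    Frame count, dimensions and rate are preserved.  At frames where a
    track has a gap (interpolated position) the circle is drawn dashed.
    The optional timer stamps seconds.milliseconds in the top-left corner.
    """
    for t in tracks:
        if t.first_frame < 0 or t.last_frame >= len(seq):
            raise ValueError(f"track {t.track_id} outside sequence range")
    frames = seq.frames
    if frames.dtype != np.uint8:
        hi = float(frames.max()) or 1.0
        frames = np.clip(frames.astype(float) / hi * 255, 0, 255).astype(np.uint8)
    rgb = np.repeat(frames[..., None], 3, axis=-1)
    h, w = seq.frame_shape
    for f in range(len(seq)):
        for i, t in enumerate(tracks):
            if not (t.first_frame <= f <= t.last_frame):
                continue
            color = _RGB_PALETTE[i % len(_RGB_PALETTE)]
            k = f - t.first_frame
            pts = np.rint(t.positions[max(0, k - trail) : k + 1]).astype(int)
            for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
                rr, cc = skdraw.line(y0, x0, y1, x1)
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                rgb[f, rr[ok], cc[ok]] = color
            cx, cy = t.entries[k].center
            rr, cc = skdraw.circle_perimeter(
                int(round(cy)), int(round(cx)), int(round(t.radius)), shape=(h, w)
            )
            if f in t.gaps:  # dashed circle flags an interpolated position
                rr, cc = rr[::2], cc[::2]
            rgb[f, rr, cc] = color
        if timer_stamp:
            ts = seq.time_of(f)
            _stamp_text(rgb[f], f"{int(ts):d}.{int(round((ts % 1) * 1000)):03d}")
    return video_io.write_video(rgb, out, frame_rate=seq.frame_rate)


def export_bundle(
    tracks: list[Track],
    traces: list[IntensityTrace],
    events_by_track: dict,
    summaries_by_track: dict,
    out_dir: str | Path,
    seq: FrameSequence | None = None,
    frame_rate: float | None = None,
    extras: dict | None = None,
) -> dict:
    """Write the full text + image + video output set; returns a manifest.

    CSVs: tracks, traces, events, summaries (schemas as exported by the
    respective modules).  Images: per-track orbit-line path PNG and the
    group time-course PNG.  Video: overlay AVI when ``seq`` is given.
    The manifest maps each artifact to its row or frame count and is also
    written as ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rate = frame_rate or (traces[0].frame_rate if traces else None)
    if rate is None:
        raise ValueError("frame_rate required when no traces are given")
    manifest: dict = {"files": {}}

    def _note(name: str, count: int) -> None:
        manifest["files"][name] = {"count": int(count)}

    try:
        df = trk.tracks_to_frame(tracks, rate)
        df.to_csv(out_dir / "tracks.csv", index=False)
        _note("tracks.csv", len(df))

        pairs = list(zip(tracks, traces))
        df = phot.traces_to_frame(pairs)
        df.to_csv(out_dir / "traces.csv", index=False)
        _note("traces.csv", len(df))

        df = fm.events_to_frame(events_by_track)
        df.to_csv(out_dir / "events.csv", index=False)
        _note("events.csv", len(df))

        df = fm.summaries_to_frame(summaries_by_track)
        df.to_csv(out_dir / "summary.csv", index=False)
        _note("summary.csv", len(df))

        if traces:
            render_timecourse(traces, out=out_dir / "timecourse.png")
            _note("timecourse.png", len(traces))
        for track, trace in pairs:
            name = f"path_{track.track_id}.png"
            img = render_path(track, trace, canvas=seq.frame_shape if seq else None)
            plt.imsave(out_dir / name, img, cmap="gray", vmin=0, vmax=255)
            _note(name, len(track))

        if seq is not None:
            write_overlay_video(seq, tracks, traces, out_dir / "overlay.avi")
            _note("overlay.avi", len(seq))
    except Exception as exc:  # pragma: no cover - partial-write reporting
        raise IOError(f"export failed while writing into {out_dir}: {exc}") from exc

    if extras:
        manifest.update(extras)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
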