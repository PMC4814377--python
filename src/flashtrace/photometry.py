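"""ROI photometry: track + frame sequence → background-corrected flash signal.

The intensity of an individual at frame *i* is the sum of pixel values
inside its circular ROI minus the local background, estimated as the median
of an annulus around the ROI (excluding pixels claimed by any other track,
so one individual's flash cannot inflate a neighbor's background).
Photometry always reads raw frames; display adjustments never enter here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tracking import Roi, Track
from .video_io import FrameSequence

__all__ = [
    "IntensityTrace",
    "estimate_background",
    "measure_intensity",
    "traces_to_frame",
    "write_traces_csv",
]


@dataclass
class IntensityTrace:
    """Background-corrected ROI brightness versus time for one track."""

    track_id: int | str
    times: np.ndarray  # seconds, spacing 1/frame_rate
    values: np.ndarray  # summed excess intensity, sensor units
    background: np.ndarray  # per-frame background estimate, units/pixel
    frame_rate: float
    frames: np.ndarray  # frame indices into the source sequence
    is_gap: np.ndarray  # True where the ROI center was interpolated

    def __post_init__(self):
        n = len(self.times)
        for name in ("values", "background", "frames", "is_gap"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def _roi_pixels(shape: tuple[int, int], center: tuple[float, float], radius: float):
    """(ys, xs) of in-frame pixels whose centers lie within the ROI circle."""
    h, w = shape
    cx, cy = center
    x0 = max(0, int(np.floor(cx - radius)))
    x1 = min(w - 1, int(np.ceil(cx + radius)))
    y0 = max(0, int(np.floor(cy - radius)))
    y1 = min(h - 1, int(np.ceil(cy + radius)))
    if x0 > x1 or y0 > y1:
        return np.array([], dtype=int), np.array([], dtype=int)
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    return ys[inside], xs[inside]


def _annulus_pixels(shape, center, radius):
    h, w = shape
    cx, cy = center
    r_out = 2.0 * radius
    x0 = max(0, int(np.floor(cx - r_out)))
    x1 = min(w - 1, int(np.ceil(cx + r_out)))
    y0 = max(0, int(np.floor(cy - r_out)))
    y1 = min(h - 1, int(np.ceil(cy + r_out)))
    if x0 > x1 or y0 > y1:
        return np.array([], dtype=int), np.array([], dtype=int)
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    ring = (d2 > radius**2) & (d2 <= r_out**2)
    return ys[ring], xs[ring]


def estimate_background(
    frame: np.ndarray,
    roi: Roi,
    exclude: list[Roi] | None = None,
    with_flag: bool = False,
):
    """Median pixel value in the annulus radius→2×radius around the ROI.

    Pixels inside any ROI in ``exclude`` (other tracks at this frame) are
    dropped.  If clipping and exclusions empty the annulus, falls back to
    the whole-frame median (flag reports this when ``with_flag``).
    """
    frame = np.asarray(frame)
    ys, xs = _annulus_pixels(frame.shape, roi.center, roi.radius)
    if exclude and len(ys):
        keep = np.ones(len(ys), dtype=bool)
        for other in exclude:
            ox, oy = other.center
            keep &= (xs - ox) ** 2 + (ys - oy) ** 2 > other.radius**2
        ys, xs = ys[keep], xs[keep]
    if len(ys) == 0:
        value, fallback = float(np.median(frame)), True
    else:
        value, fallback = float(np.median(frame[ys, xs])), False
    return (value, fallback) if with_flag else value


def measure_intensity(
    seq: FrameSequence,
    track: Track,
    others: list[Track] | None = None,
    aggregate: str = "sum",
    clip_negative: bool = True,
) -> IntensityTrace:
    """Measure the track's background-corrected ROI intensity per frame.

    ``aggregate`` is ``"sum"`` (total excess flux; robust to ROI radius for
    an enclosed point source, the default) or ``"mean"`` (per-pixel mean).
    ROI pixels falling outside the frame are excluded from the sum; a
    negative net value clips to zero unless ``clip_negative=False``.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")
    if track.first_frame < 0 or track.last_frame >= len(seq):
        raise ValueError(
            f"track frames [{track.first_frame}, {track.last_frame}] outside "
            f"sequence of {len(seq)} frames"
        )
    others = others or []
    by_frame_others: dict[int, list[Roi]] = {}
    for other in others:
        if other is track or other.track_id == track.track_id:
            continue
        for roi in other.entries:
            by_frame_others.setdefault(roi.frame_index, []).append(roi)

    values = np.empty(len(track))
    bg = np.empty(len(track))
    for i, roi in enumerate(track.entries):
        frame = seq.frames[roi.frame_index]
        b = estimate_background(frame, roi, by_frame_others.get(roi.frame_index))
        ys, xs = _roi_pixels(frame.shape, roi.center, roi.radius)
        if len(ys) == 0:
            v = 0.0
        else:
            excess = frame[ys, xs].astype(np.float64) - b
            v = float(excess.sum()) if aggregate == "sum" else float(excess.mean())
        if clip_negative and v < 0:
            v = 0.0
        values[i] = v
        bg[i] = b

    frames = track.frames
    times = seq.t0 + frames / seq.frame_rate
    is_gap = np.array([f in track.gaps for f in frames])
    return IntensityTrace(track.track_id, times, values, bg, seq.frame_rate, frames, is_gap)


def traces_to_frame(pairs: list[tuple[Track, IntensityTrace]]) -> pd.DataFrame:
    """Tabulate (track, trace) pairs as the frame-by-frame coordinates +
    light-intensity table: ``track_id,frame,time_s,x,y,intensity,background,is_gap``."""
    rows = []
    for track, trace in pairs:
        pos = track.positions
        for i in range(len(trace)):
            rows.append(
                {
                    "track_id": trace.track_id,
                    "frame": int(trace.frames[i]),
                    "time_s": trace.times[i],
                    "x": pos[i, 0],
                    "y": pos[i, 1],
                    "intensity": trace.values[i],
                    "background": trace.background[i],
                    "is_gap": bool(trace.is_gap[i]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "time_s", "x", "y", "intensity", "background", "is_gap"],
    )


def write_traces_csv(pairs: list[tuple[Track, IntensityTrace]], path: str | Path) -> Path:
    traces_to_frame(pairs).to_csv(path, index=False)
    return Path(path)
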