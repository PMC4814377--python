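"""Per-individual flight paths: manual-trace import and automated spot tracking.

The reference workflow assigns one circular region of interest (ROI) per
individual and follows it frame by frame; here a track comes either from a
manual trace CSV (columns ``frame,x,y``) or from thresholded spot detection
linked frame-to-frame by greedy nearest-neighbor assignment.

Tracks may superpose: when two flight paths coincide the two ROIs simply
overlap, and the individual intensities are no longer separable — a warning
is logged, matching the limitation of tracing by eye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

log = logging.getLogger(__name__)

__all__ = [
    "Roi",
    "Track",
    "Detection",
    "load_manual_track",
    "load_manual_tracks",
    "detect_spots",
    "link_tracks",
    "tracks_to_frame",
    "write_tracks_csv",
]


@dataclass(frozen=True)
class Roi:
    """Circular region of interest at one frame.

    A pixel belongs to the ROI iff the Euclidean distance from its integer
    coordinate to ``center`` is ≤ ``radius``.
    """

    center: tuple[float, float]  # (x, y)
    radius: float
    frame_index: int

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError(f"ROI radius must be ≥ 1 px, got {self.radius}")


@dataclass
class Track:
    """One individual's ROI per frame over a contiguous frame range.

    ``entries`` covers every frame from first to last; frames with no
    observation (interpolated centers) are listed in ``gaps``.
    """

    track_id: int | str
    entries: list[Roi]
    gaps: set[int] = field(default_factory=set)

    def __post_init__(self):
        frames = [r.frame_index for r in self.entries]
        if not frames:
            raise ValueError("a track needs at least one entry")
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track entries must cover a contiguous, increasing frame range")
        radii = {r.radius for r in self.entries}
        if len(radii) > 1:
            raise ValueError("ROI radius must be constant within a track")

    @property
    def first_frame(self) -> int:
        return self.entries[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.entries[-1].frame_index

    @property
    def radius(self) -> float:
        return self.entries[0].radius

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.first_frame, self.last_frame + 1)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) centers, one row per covered frame."""
        return np.array([r.center for r in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)

    def extended(self, first_frame: int, last_frame: int) -> "Track":
        """Extend the covered range, holding the boundary centers fixed.

        Added frames carry no observation and are recorded as gaps.  Used
        when the tracked source is invisible outside its luminous phases
        but its ROI should still be measured over the whole sequence.
        """
        if first_frame > self.first_frame or last_frame < self.last_frame:
            raise ValueError("extended range must contain the track's range")
        r = self.radius
        head = [
            Roi(self.entries[0].center, r, f) for f in range(first_frame, self.first_frame)
        ]
        tail = [
            Roi(self.entries[-1].center, r, f)
            for f in range(self.last_frame + 1, last_frame + 1)
        ]
        gaps = set(self.gaps)
        gaps.update(r_.frame_index for r_ in head)
        gaps.update(r_.frame_index for r_ in tail)
        return Track(self.track_id, head + list(self.entries) + tail, gaps)


@dataclass(frozen=True)
class Detection:
    """A connected bright spot in one frame."""

    centroid: tuple[float, float]  # (x, y), brightness-weighted, sub-pixel
    total_brightness: float
    area: int


def _interpolate_entries(
    observed: list[tuple[int, tuple[float, float]]], radius: float
) -> tuple[list[Roi], set[int]]:
    """Fill missing interior frames by linear interpolation of centers."""
    frames = np.array([f for f, _ in observed])
    xs = np.array([c[0] for _, c in observed])
    ys = np.array([c[1] for _, c in observed])
    full = np.arange(frames[0], frames[-1] + 1)
    fx = np.interp(full, frames, xs)
    fy = np.interp(full, frames, ys)
    gaps = set(full) - set(frames.tolist())
    entries = [Roi((float(x), float(y)), radius, int(f)) for f, x, y in zip(full, fx, fy)]
    return entries, gaps


def load_manual_track(path: str | Path, radius: float, track_id: int | str = 0) -> Track:
    """Load one individual's manual trace CSV (header ``frame,x,y``).

    Frames are 0-based and must be strictly increasing; frames missing
    between the first and last become gaps with interpolated centers.
    """
    df = pd.read_csv(path)
    required = {"frame", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manual trace needs columns {sorted(required)}, has {list(df.columns)}")
    for col in ("frame", "x", "y"):
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            raise ValueError(f"{path}: non-numeric or missing values in column {col!r}")
    frames = df["frame"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        raise ValueError(f"{path}: frame indices must be strictly increasing")
    observed = [
        (int(f), (float(x), float(y)))
        for f, x, y in zip(frames, df["x"].to_numpy(), df["y"].to_numpy())
    ]
    entries, gaps = _interpolate_entries(observed, radius)
    return Track(track_id, entries, gaps)


def load_manual_tracks(path: str | Path, radius: float) -> list[Track]:
    """Load a multi-individual trace CSV with columns ``frame,x,y,track_id``."""
    df = pd.read_csv(path)
    if "track_id" not in df.columns:
        return [load_manual_track(path, radius)]
    tracks = []
    for tid, group in df.groupby("track_id", sort=True):
        frames = group["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"{path}: track {tid}: frame indices must be strictly increasing")
        observed = [
            (int(f), (float(x), float(y)))
            for f, x, y in zip(frames, group["x"].to_numpy(), group["y"].to_numpy())
        ]
        entries, gaps = _interpolate_entries(observed, radius)
        tracks.append(Track(tid, entries, gaps))
    return tracks


def detect_spots(frame: np.ndarray, threshold: float, min_area: int = 1) -> list[Detection]:
    """Find connected components of pixels brighter than ``threshold``.

    Centroids are brightness-weighted means of the component's pixel
    coordinates; the list is sorted by descending total brightness (ties
    broken by position) so ordering is deterministic.
    """
    frame = np.asarray(frame)
    mask = frame > threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    dets = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area < min_area:
            continue
        total = float(region.image_intensity[region.image].sum())
        cy, cx = region.centroid_weighted
        dets.append(Detection((float(cx), float(cy)), total, int(region.area)))
    dets.sort(key=lambda d: (-d.total_brightness, d.centroid[0], d.centroid[1]))
    return dets


def link_tracks(
    detections_per_frame: list[list[Detection]],
    max_jump: float,
    max_gap: int = 2,
    roi_radius: float = 5.0,
    min_obs: int = 1,
) -> list[Track]:
    """Link per-frame detections into tracks by greedy nearest-neighbor.

    Candidate (track, detection) pairs within ``max_jump`` pixels are
    assigned in order of increasing distance; at equal distance the lower
    track id wins.  A detection matching no live track starts a new track;
    a track unmatched for more than ``max_gap`` consecutive frames is
    closed.  Interior unmatched frames become gaps with linearly
    interpolated centers.  Tracks with fewer than ``min_obs`` observations
    (e.g. single-frame noise blips) are discarded.
    """

    class _Live:
        __slots__ = ("tid", "observed", "last_frame")

        def __init__(self, tid, frame, center):
            self.tid = tid
            self.observed = [(frame, center)]
            self.last_frame = frame

    live: list[_Live] = []
    closed: list[_Live] = []
    next_id = 0

    for f, dets in enumerate(detections_per_frame):
        centers = [d.centroid for d in dets]
        pairs = []
        for t in live:
            lx, ly = t.observed[-1][1]
            for j, (dx, dy) in enumerate(centers):
                dist = float(np.hypot(dx - lx, dy - ly))
                if dist <= max_jump:
                    pairs.append((dist, t.tid, j, t))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tid, j, t in pairs:
            if tid in used_tracks or j in used_dets:
                continue
            t.observed.append((f, centers[j]))
            t.last_frame = f
            used_tracks.add(tid)
            used_dets.add(j)
        for j in range(len(centers)):
            if j not in used_dets:
                nt = _Live(next_id, f, centers[j])
                next_id += 1
                live.append(nt)
        still_live = []
        for t in live:
            if f - t.last_frame > max_gap:
                closed.append(t)
            else:
                still_live.append(t)
        live = still_live

        obs_now = [t.observed[-1][1] for t in live if t.last_frame == f]
        for i in range(len(obs_now)):
            for k in range(i + 1, len(obs_now)):
                if np.hypot(
                    obs_now[i][0] - obs_now[k][0], obs_now[i][1] - obs_now[k][1]
                ) <= roi_radius:
                    log.warning(
                        "two track centers within one ROI radius at frame %d; "
                        "their intensities are not separable",
                        f,
                    )

    closed.extend(live)
    closed.sort(key=lambda t: t.tid)
    tracks = []
    for t in closed:
        if len(t.observed) < min_obs:
            continue
        entries, gaps = _interpolate_entries(t.observed, roi_radius)
        tracks.append(Track(t.tid, entries, gaps))
    return tracks


def tracks_to_frame(tracks: list[Track], frame_rate: float, t0: float = 0.0) -> pd.DataFrame:
    """Tabulate tracks as ``track_id,frame,time_s,x,y,is_gap`` rows."""
    rows = []
    for t in tracks:
        for roi in t.entries:
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": roi.frame_index,
                    "time_s": t0 + roi.frame_index / frame_rate,
                    "x": roi.center[0],
                    "y": roi.center[1],
                    "is_gap": roi.frame_index in t.gaps,
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "time_s", "x", "y", "is_gap"])


def write_tracks_csv(tracks: list[Track], frame_rate: float, path: str | Path, t0: float = 0.0) -> Path:
    tracks_to_frame(tracks, frame_rate, t0).to_csv(path, index=False)
    return Path(path)
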