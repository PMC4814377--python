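"""Frame-sequence loading, trimming, export, and non-destructive display adjustment.

A recording enters the pipeline either as an AVI file or as a directory of
numbered single-frame images (TIFF/PNG) — the two dialects are
interchangeable everywhere.  Color input is collapsed to luminance at load,
since all downstream photometry works on a single intensity value per pixel.

Coordinate convention, used package-wide: 0-based pixel indices, origin at
the top-left, x rightward, y downward, pixel centers on integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from . import _avi

__all__ = [
    "FrameSequence",
    "DisplayAdjustment",
    "read_video",
    "export_frames",
    "trim",
    "adjust_display",
    "rgb_to_luminance",
]

#: Rec. 601 luma weights for collapsing RGB to a single intensity channel.
_LUMA = np.array([0.299, 0.587, 0.114])

_STACK_EXTENSIONS = (".tif", ".tiff", ".png")


@dataclass(frozen=True)
class FrameSequence:
    """Ordered stack of equally-shaped grayscale frames at a constant rate.

    frames holds an (n, h, w) array in the sensor's native integer units;
    the timestamp of frame ``i`` is ``t0 + i / frame_rate``.
    """

    frames: np.ndarray
    frame_rate: float
    t0: float = 0.0

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, h, w) stack")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def times(self) -> np.ndarray:
        """Per-frame timestamps in seconds, strictly increasing."""
        return self.t0 + np.arange(len(self)) / self.frame_rate

    def time_of(self, frame_index: int) -> float:
        return self.t0 + frame_index / self.frame_rate


@dataclass(frozen=True)
class DisplayAdjustment:
    """Brightness/contrast transform applied only at render time.

    ``out = clip(gain * value + offset)``.  Never touches the stored
    frames and never feeds photometry.
    """

    gain: float = 1.0
    offset: float = 0.0


def rgb_to_luminance(rgb: np.ndarray) -> np.ndarray:
    """Collapse an (..., 3) RGB raster to luminance, keeping the input dtype."""
    rgb = np.asarray(rgb)
    if rgb.shape[-1] != 3:
        raise ValueError("expected trailing RGB axis of size 3")
    # R == G == B is the common case for night recordings stored as RGB;
    # take the channel directly so round trips stay bit-exact.
    if np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2]):
        return rgb[..., 0].copy()
    luma = rgb.astype(np.float64) @ _LUMA
    if np.issubdtype(rgb.dtype, np.integer):
        return np.rint(luma).astype(rgb.dtype)
    return luma.astype(rgb.dtype)


def _read_frame_stack(directory: Path) -> np.ndarray:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _STACK_EXTENSIONS
    )
    if not files:
        raise IOError(f"{directory}: no TIFF/PNG frames found")
    frames = []
    for p in files:
        if p.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(p)
        else:
            import imageio.v3 as iio

            img = iio.imread(p)
        if img.ndim == 3:
            img = rgb_to_luminance(img[..., :3])
        frames.append(img)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise IOError(f"{directory}: frames differ in shape: {sorted(shapes)}")
    return np.stack(frames)


def read_video(path: str | Path, frame_rate: float | None = None, t0: float = 0.0) -> FrameSequence:
    """Load an AVI file or a frame-stack directory as a FrameSequence.

    ``frame_rate`` overrides the container's metadata; for frame stacks,
    which carry no rate, it is required.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file or directory")
    if path.is_dir():
        frames = _read_frame_stack(path)
        if frame_rate is None:
            raise ValueError(
                f"{path}: a frame-stack directory carries no frame rate; pass frame_rate="
            )
        return FrameSequence(frames, frame_rate, t0)
    rgb, fps = _avi.read_avi(path)
    rate = frame_rate if frame_rate is not None else fps
    if not rate or rate <= 0:
        raise ValueError(f"{path}: no frame rate in container metadata; pass frame_rate=")
    return FrameSequence(rgb_to_luminance(rgb), rate, t0)


def export_frames(seq: FrameSequence, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Save each frame as an uncompressed TIFF named ``<prefix>_%06d.tif``.

    Re-reading the directory with :func:`read_video` yields pixel-identical
    frames for integer rasters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(seq)):
        p = out_dir / f"{prefix}_{i:06d}.tif"
        tifffile.imwrite(p, seq.frames[i])
        paths.append(p)
    return paths


def write_video(seq_or_frames, path: str | Path, frame_rate: float | None = None) -> Path:
    """Write frames to an uncompressed AVI (8-bit; grayscale replicated to RGB)."""
    if isinstance(seq_or_frames, FrameSequence):
        frames, rate = seq_or_frames.frames, seq_or_frames.frame_rate
    else:
        frames, rate = np.asarray(seq_or_frames), frame_rate
    if rate is None:
        raise ValueError("frame_rate required when writing a bare array")
    if frames.dtype != np.uint8:
        info = np.iinfo(frames.dtype) if np.issubdtype(frames.dtype, np.integer) else None
        if info is not None and info.max > 255:
            frames = (frames.astype(np.uint32) >> (info.bits - 8)).astype(np.uint8)
        else:
            frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return _avi.write_avi(path, frames, rate)


def trim(seq: FrameSequence, start_frame: int, end_frame: int) -> FrameSequence:
    """Return frames ``[start_frame, end_frame)`` with t0 advanced accordingly."""
    if not (0 <= start_frame < end_frame <= len(seq)):
        raise ValueError(
            f"trim bounds [{start_frame}, {end_frame}) invalid for {len(seq)}-frame sequence"
        )
    return replace(
        seq,
        frames=seq.frames[start_frame:end_frame].copy(),
        t0=seq.t0 + start_frame / seq.frame_rate,
    )


def adjust_display(frame: np.ndarray, adj: DisplayAdjustment) -> np.ndarray:
    """Apply gain/offset for rendering, clipped to the raster's range.

    The input is never modified; photometry must always read raw frames.
    """
    frame = np.asarray(frame)
    out = frame.astype(np.float64) * adj.gain + adj.offset
    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(frame.dtype)
    return out.astype(frame.dtype)
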