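"""Minimal uncompressed AVI (RIFF / BI_RGB DIB) reader and writer.

Supports exactly what the pipeline needs: single-video-stream AVI files
with uncompressed DIB frames, 8-bit paletted or 24/32-bit BGR(X).  Rows
are stored bottom-up and padded to 4-byte boundaries, per the DIB spec.
Frame rate is carried as the stream's rate/scale rational.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_avi", "write_avi"]

_AVIF_HASINDEX = 0x00000010


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    if len(fourcc) != 4:
        raise ValueError("fourcc must be 4 bytes")
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> Path:
    """Write frames as an uncompressed 24-bit DIB AVI.

    frames: (n, h, w) grayscale or (n, h, w, 3) RGB, uint8.
    Grayscale is replicated into B=G=R so any AVI reader (including
    :func:`read_avi` followed by luminance conversion) recovers the
    original values exactly.
    """
    frames = np.asarray(frames)
    if frames.ndim == 3:
        rgb = np.repeat(frames[..., None], 3, axis=-1)
    elif frames.ndim == 4 and frames.shape[-1] == 3:
        rgb = frames
    else:
        raise ValueError(f"expected (n,h,w) or (n,h,w,3) array, got {frames.shape}")
    if rgb.dtype != np.uint8:
        raise ValueError("AVI writer accepts uint8 frames only")
    if fps <= 0:
        raise ValueError("fps must be positive")

    n, h, w = rgb.shape[:3]
    row_bytes = w * 3
    padded = (row_bytes + 3) & ~3
    frame_bytes = padded * h

    # fps as a rational with millihertz resolution
    rate = int(round(fps * 1000))
    scale = 1000

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # microseconds per frame
        frame_bytes * int(np.ceil(fps)),  # max bytes/sec (advisory)
        0,  # padding granularity
        _AVIF_HASINDEX,
        n,  # total frames
        0,  # initial frames
        1,  # streams
        frame_bytes,  # suggested buffer size
        w,
        h,
        0, 0, 0, 0,
    )
    strh = (
        b"vids" + b"DIB "
        + struct.pack("<IHHIIIIIIII", 0, 0, 0, 0, scale, rate, 0, n, frame_bytes, 0xFFFFFFFF, 0)
        + struct.pack("<4h", 0, 0, w, h)
    )
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)

    hdrl = _list(
        b"hdrl",
        _chunk(b"avih", avih) + _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)),
    )

    movi_parts = []
    index_entries = []
    offset = 4  # relative to start of 'movi' fourcc
    for i in range(n):
        # bottom-up BGR rows, padded
        bgr = rgb[i, ::-1, :, ::-1]
        buf = np.zeros((h, padded), dtype=np.uint8)
        buf[:, :row_bytes] = bgr.reshape(h, row_bytes)
        data = buf.tobytes()
        movi_parts.append(_chunk(b"00db", data))
        index_entries.append(struct.pack("<4sIII", b"00db", 0x10, offset, len(data)))
        offset += 8 + len(data) + (len(data) % 2)
    movi = _list(b"movi", b"".join(movi_parts))
    idx1 = _chunk(b"idx1", b"".join(index_entries))

    riff_payload = b"AVI " + hdrl + movi + idx1
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)
    return path


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed DIB AVI; returns (frames (n,h,w,3) uint8 RGB, fps)."""
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise IOError(f"{path}: not a RIFF/AVI file")

    fps = None
    width = height = None
    bitcount = None
    palette = None
    frames: list[np.ndarray] = []

    def walk(start: int, end: int) -> None:
        nonlocal fps, width, height, bitcount, palette
        for fourcc, dstart, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(dstart + 4, dstart + size)
            elif fourcc == b"strh":
                fcc_type = buf[dstart : dstart + 4]
                if fcc_type == b"vids":
                    scale, rate = struct.unpack_from("<II", buf, dstart + 20)
                    if scale > 0 and rate > 0:
                        fps = rate / scale
            elif fourcc == b"strf" and width is None:
                (bisize, w, h, _planes, bits, compression) = struct.unpack_from(
                    "<IiiHHI", buf, dstart
                )
                if compression != 0:
                    raise IOError(
                        f"{path}: compressed AVI (fourcc {compression:#x}) not supported; "
                        "use an uncompressed DIB AVI or a frame-stack directory"
                    )
                width, height, bitcount = w, abs(h), bits
                if bits == 8:
                    pal = np.frombuffer(
                        buf, dtype=np.uint8, count=256 * 4, offset=dstart + bisize
                    ).reshape(256, 4)
                    palette = pal[:, 2::-1].copy()  # BGRX -> RGB
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames.append(_decode_dib(buf[dstart : dstart + size], width, height, bitcount, palette))

    walk(12, len(buf))
    if not frames:
        raise IOError(f"{path}: no video frames found")
    return np.stack(frames), float(fps if fps else 0.0)


def _decode_dib(data: bytes, w: int, h: int, bits: int, palette) -> np.ndarray:
    if w is None or bits is None:
        raise IOError("AVI frame data encountered before stream format header")
    if bits == 8:
        padded = (w + 3) & ~3
        idx = np.frombuffer(data, dtype=np.uint8, count=padded * h).reshape(h, padded)[::-1, :w]
        if palette is not None:
            return palette[idx]
        return np.repeat(idx[..., None], 3, axis=-1)
    if bits in (24, 32):
        nch = bits // 8
        padded = (w * nch + 3) & ~3
        rows = np.frombuffer(data, dtype=np.uint8, count=padded * h).reshape(h, padded)
        bgr = rows[::-1, : w * nch].reshape(h, w, nch)
        return bgr[..., 2::-1][..., :3].copy()
    raise IOError(f"unsupported DIB bit depth {bits}")
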