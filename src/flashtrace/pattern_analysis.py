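"""Downstream signal analyses: flash synchrony, spectral content, path fractality.

These operate on the exported time-series products — intensity traces and
coordinate tracks — and quantify what a field observer describes
qualitatively: how synchronous a group's flashing is (pairwise lagged
Pearson correlation), what rhythm the flash train carries (periodogram),
and how convoluted a flight path is (box-counting fractal dimension,
1 for a straight line, 2 for a plane-filling path).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .photometry import IntensityTrace
from .tracking import Track

__all__ = [
    "SynchronyResult",
    "SpectrumResult",
    "PathMetrics",
    "cross_correlate",
    "pairwise_synchrony",
    "binarize_trace",
    "power_spectrum",
    "fractal_dimension",
]


@dataclass(frozen=True)
class SynchronyResult:
    """Lagged Pearson correlation between two individuals' flash signals."""

    track_pair: tuple
    corr_zero_lag: float
    best_lag: float  # seconds; positive = second trace lags the first
    corr_at_best_lag: float
    lags: np.ndarray  # seconds
    correlogram: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "correlation": self.correlogram})


@dataclass(frozen=True)
class SpectrumResult:
    """One-sided periodogram of a mean-removed intensity trace."""

    frequencies: np.ndarray  # Hz, 0 … frame_rate/2
    power: np.ndarray  # sensor-units² per Hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_hz": self.frequencies, "power": self.power})


@dataclass(frozen=True)
class PathMetrics:
    """Box-counting scaling of a flight path."""

    box_sizes: np.ndarray  # pixels, descending dyadic ladder
    box_counts: np.ndarray
    dimension: float
    fit_r2: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"box_size_px": self.box_sizes, "box_count": self.box_counts})
        df["dimension"] = self.dimension
        df["fit_r2"] = self.fit_r2
        return df


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt((x * x).sum() * (y * y).sum())
    if den == 0:
        return np.nan
    return float((x * y).sum() / den)


def cross_correlate(a: IntensityTrace, b: IntensityTrace, max_lag: float) -> SynchronyResult:
    """Pearson correlation of two traces at every integer-frame lag in ±max_lag.

    At lag τ the correlation compares ``a(t)`` with ``b(t + τ)``, so a
    positive best lag means b is a delayed copy of a.  Each lag uses the
    overlapping window only, mean-removed and variance-normalized; at
    least 3 overlapping samples are required at every evaluated lag.
    """
    if a.frame_rate != b.frame_rate:
        raise ValueError("traces must share a frame rate")
    va, vb = np.asarray(a.values, float), np.asarray(b.values, float)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("correlation undefined for a zero-variance trace")
    dt = 1.0 / a.frame_rate
    L = int(round(max_lag / dt))
    lags = np.arange(-L, L + 1)
    corr = np.empty(len(lags))
    for i, k in enumerate(lags):
        # overlap of a[j] with b[j + k]
        j0 = max(0, -k)
        j1 = min(len(va), len(vb) - k)
        if j1 - j0 < 3:
            raise ValueError(f"fewer than 3 overlapping samples at lag {k} frames")
        corr[i] = _pearson(va[j0:j1], vb[j0 + k : j1 + k])
    finite = np.isfinite(corr)
    if not finite.any():
        raise ValueError("correlation undefined at every lag")
    cmax = np.nanmax(corr)
    candidates = np.flatnonzero(finite & (corr == cmax))
    best = min(candidates, key=lambda i: (abs(int(lags[i])), int(lags[i])))
    zero = int(np.flatnonzero(lags == 0)[0])
    return SynchronyResult(
        track_pair=(a.track_id, b.track_id),
        corr_zero_lag=float(corr[zero]),
        best_lag=float(lags[best] * dt),
        corr_at_best_lag=float(corr[best]),
        lags=lags * dt,
        correlogram=corr,
    )


def pairwise_synchrony(
    traces: list[IntensityTrace], max_lag: float
) -> tuple[list[SynchronyResult], float]:
    """All pairwise correlations plus the group synchrony index.

    The group index is the mean zero-lag correlation over all pairs — a
    concrete reading of "degree of synchrony among individuals".
    """
    results = []
    for i in range(len(traces)):
        for j in range(i + 1, len(traces)):
            results.append(cross_correlate(traces[i], traces[j], max_lag))
    group = float(np.mean([r.corr_zero_lag for r in results])) if results else np.nan
    return results, group


def binarize_trace(trace: IntensityTrace, events) -> IntensityTrace:
    """0/1 flash train from segmented events, for event-level synchrony."""
    on = np.zeros(len(trace))
    for e in events:
        on[(trace.times >= e.onset) & (trace.times <= e.offset)] = 1.0
    return IntensityTrace(
        trace.track_id, trace.times, on, np.zeros(len(trace)),
        trace.frame_rate, trace.frames, trace.is_gap,
    )


def power_spectrum(trace: IntensityTrace, taper: str | None = None) -> SpectrumResult:
    """One-sided periodogram (power spectral density) of the mean-removed trace.

    No taper by default; pass a scipy window name (e.g. ``"hann"``) to
    trade leakage against resolution.  Satisfies Parseval: the integrated
    density equals the trace variance.
    """
    if len(trace) < 8:
        raise ValueError("need a trace of ≥ 8 samples for a spectrum")
    window = taper if taper is not None else "boxcar"
    f, p = sps.periodogram(
        np.asarray(trace.values, float),
        fs=trace.frame_rate,
        window=window,
        detrend="constant",
        scaling="density",
    )
    return SpectrumResult(f, p)


def _densify(points: np.ndarray, spacing: float = 0.5) -> np.ndarray:
    """Resample a polyline so consecutive samples are ≤ spacing apart."""
    out = [points[:1]]
    for p, q in zip(points[:-1], points[1:]):
        d = float(np.hypot(*(q - p)))
        n = max(1, int(np.ceil(d / spacing)))
        ts = np.linspace(0, 1, n + 1)[1:, None]
        out.append(p + ts * (q - p))
    return np.vstack(out)


def fractal_dimension(track: Track | np.ndarray, n_scales: int = 6) -> PathMetrics:
    """Box-counting dimension of a planar path.

    The polyline through consecutive centers is densified by linear
    interpolation (so sparse sampling cannot starve small boxes), overlaid
    with grids anchored at the path's bounding-box corner, of dyadic box
    sizes from the bounding box's larger dimension down ``n_scales``
    halvings (smallest box ≥ 2 px).  The dimension is the least-squares
    slope of log(count) versus log(1/size).
    """
    pts = track.positions if isinstance(track, Track) else np.asarray(track, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (x, y) positions")
    if len(np.unique(pts, axis=0)) < 2:
        raise ValueError("path needs at least 2 distinct positions")
    dense = _densify(pts)
    origin = dense.min(axis=0)
    extent = dense.max(axis=0) - origin
    s0 = float(extent.max())
    sizes = [s0 / 2**k for k in range(n_scales) if s0 / 2**k >= 2.0]
    if len(sizes) < 2:
        sizes = [s0, s0 / 2]
    rel = dense - origin
    # keep boundary points inside the last box of their row/column
    rel = np.minimum(rel, np.maximum(extent - 1e-9, 0))
    counts = []
    for s in sizes:
        idx = np.floor(rel / s).astype(np.int64)
        counts.append(len(np.unique(idx, axis=0)))
    x = np.log(1.0 / np.asarray(sizes))
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    if 2.0 < slope < 2.0 + 1e-6:  # planar bound exceeded only by round-off
        slope = 2.0
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PathMetrics(np.asarray(sizes), np.asarray(counts), float(slope), r2)
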