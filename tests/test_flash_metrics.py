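import numpy as np
import pytest

from flashtrace.flash_metrics import (
    FlashEvent,
    detect_peaks,
    segment_flashes,
    summarize,
)
from flashtrace.synthetic import FlashSpec


def brute_force_peaks(values):
    """Oracle: strict local maxima with directly computed prominence."""
    peaks = []
    for i in range(1, len(values) - 1):
        if values[i] > values[i - 1] and values[i] > values[i + 1]:
            left = values[:i][::-1]
            right = values[i + 1 :]

            def base(side):
                lowest = values[i]
                for v in side:
                    if v > values[i]:
                        break
                    lowest = min(lowest, v)
                return lowest

            prominence = values[i] - max(base(left), base(right))
            peaks.append((i, prominence))
    return peaks


class TestDetectPeaks:
    def test_constant_trace_has_no_peaks(self, trace_factory):
        assert len(detect_peaks(trace_factory(np.full(30, 5.0)))) == 0

    def test_triangular_pulse_peak_time(self, trace_factory):
        fps = 10.0
        t = np.arange(41) / fps
        v = np.maximum(0.0, 1.0 - abs(t - 2.0))
        assert detect_peaks(trace_factory(v, frame_rate=fps)) == pytest.approx([2.0])

    def test_plateau_reports_center(self, trace_factory):
        v = np.zeros(20)
        v[8:13] = 10.0  # flat top, frames 8..12
        peaks = detect_peaks(trace_factory(v, frame_rate=10.0))
        assert peaks == pytest.approx([1.0])  # center frame 10

    def test_pulse_train_matches_brute_force_oracle(self, trace_factory):
        fps = 30.0
        t = np.arange(int(8 * fps)) / fps
        v = np.zeros_like(t)
        for c in (0.5, 2.4, 4.3, 6.2):
            v += np.exp(-((t - c) ** 2) / (2 * 0.2**2))
        trace = trace_factory(v, frame_rate=fps)
        got = detect_peaks(trace, min_prominence_frac=0.5)
        span = v.max() - v.min()
        oracle = [t[i] for i, p in brute_force_peaks(v) if p >= 0.5 * span]
        assert got == pytest.approx(oracle)
        assert got == pytest.approx([0.5, 2.4, 4.3, 6.2], abs=0.5 / fps)

    def test_too_short_trace_rejected(self, trace_factory):
        with pytest.raises(ValueError):
            detect_peaks(trace_factory([1.0, 2.0]))


def rect_trace(make, fps=30.0, windows=((1.0, 2.0),), amp=100.0, total=3.5):
    t = np.arange(int(total * fps)) / fps
    v = np.zeros_like(t)
    for a, b in windows:
        v[(t >= a) & (t < b)] = amp
    return make(v, frame_rate=fps)


class TestSegmentFlashes:
    def test_rectangular_pulse_boundaries(self, trace_factory):
        fps = 30.0
        events = segment_flashes(rect_trace(trace_factory, fps))
        assert len(events) == 1
        e = events[0]
        assert e.duration == pytest.approx(1.0, abs=1 / fps)
        assert e.n_peaks == 1
        assert e.peak_times[0] == pytest.approx(1.5, abs=1 / fps)

    def test_close_subpulses_merge_into_one_event(self, trace_factory):
        fps = 50.0
        trace = rect_trace(trace_factory, fps, windows=((1.0, 1.3), (1.44, 1.74)), total=3.0)
        events = segment_flashes(trace, merge_gap=0.3)
        assert len(events) == 1
        assert events[0].n_peaks == 2
        sub = np.diff(events[0].peak_times)[0]
        # sub-pulse peak spacing equals the window spacing (0.44 s between
        # pulse centers) within one frame period
        assert sub == pytest.approx(0.44, abs=1 / fps)

    def test_small_merge_gap_keeps_events_separate(self, trace_factory):
        fps = 50.0
        trace = rect_trace(trace_factory, fps, windows=((1.0, 1.3), (1.44, 1.74)), total=3.0)
        events = segment_flashes(trace, merge_gap=0.05)
        assert len(events) == 2

    def test_zero_merge_gap_equals_plain_thresholding(self, trace_factory):
        """Oracle: direct above-threshold run segmentation with interpolated
        boundaries (equal-amplitude pulses, so per-segment == global threshold)."""
        fps = 40.0
        windows = ((0.5, 1.0), (1.6, 2.1), (2.7, 3.2))
        trace = rect_trace(trace_factory, fps, windows=windows, total=4.0)
        events = segment_flashes(trace, onset_frac=0.1, merge_gap=0.0)
        t, v = trace.times, trace.values
        baseline = np.percentile(v, 10)
        thr = baseline + 0.1 * (v.max() - baseline)
        above = v > thr
        oracle = []
        start = None
        for i, a in enumerate(above):
            if a and start is None:
                start = i
            elif not a and start is not None:
                onset = t[start - 1] + (thr - v[start - 1]) / (v[start] - v[start - 1]) * (
                    t[start] - t[start - 1]
                ) if start > 0 else t[0]
                offset = t[i - 1] + (thr - v[i - 1]) / (v[i] - v[i - 1]) * (t[i] - t[i - 1])
                oracle.append((onset, offset))
                start = None
        assert len(events) == len(oracle) == 3
        for e, (onset, offset) in zip(events, oracle):
            assert e.onset == pytest.approx(onset)
            assert e.offset == pytest.approx(offset)

    def test_flat_trace_yields_no_events(self, trace_factory):
        assert segment_flashes(trace_factory(np.full(60, 4.0))) == []

    def test_unequal_amplitudes_bounded_per_event(self, trace_factory):
        fps = 30.0
        t = np.arange(int(6 * fps)) / fps
        v = np.zeros_like(t)
        v[(t >= 1.0) & (t < 2.0)] = 100.0
        v[(t >= 4.0) & (t < 5.0)] = 20.0  # five-fold dimmer flash
        events = segment_flashes(trace_factory(v, frame_rate=fps))
        assert len(events) == 2
        for e in events:
            assert e.duration == pytest.approx(1.0, abs=1 / fps)

    @pytest.mark.parametrize("shift", [0.0, 2.5])
    @pytest.mark.parametrize("scale", [1.0, 7.3])
    def test_time_shift_and_amplitude_scale_equivariance(self, trace_factory, shift, scale):
        fps = 30.0
        base = rect_trace(trace_factory, fps, windows=((1.0, 1.4), (2.3, 2.8)), total=4.0)
        moved = trace_factory(scale * base.values, frame_rate=fps, t0=shift)
        ev0 = segment_flashes(base)
        ev1 = segment_flashes(moved)
        assert len(ev0) == len(ev1)
        for a, b in zip(ev0, ev1):
            assert b.onset == pytest.approx(a.onset + shift)
            assert b.duration == pytest.approx(a.duration)
            assert np.asarray(b.peak_times) == pytest.approx(np.asarray(a.peak_times) + shift)


class TestRecoveryFromEnvelopes:
    """Sampled simulator envelopes at 30 fps: every recovered metric within
    one frame period of the envelope's own truth, over ≥20 flashes."""

    @pytest.mark.parametrize(
        "flash",
        [
            FlashSpec("rectangular", flash_duration=0.8, period=1.7, amplitude=100.0),
            FlashSpec("raised_cosine", flash_duration=1.3, period=1.9, amplitude=100.0),
            FlashSpec(
                "raised_cosine", flash_duration=0.566, period=1.19, amplitude=100.0,
                n_subpulses=2, subpulse_interval=0.14,
            ),
        ],
        ids=["rectangular", "raised-cosine", "double-pulsed"],
    )
    def test_metric_recovery(self, trace_factory, flash):
        fps = 30.0
        n_flashes = 22
        total = flash.period * (n_flashes + 1)
        t = np.arange(int(total * fps)) / fps
        flash = FlashSpec(**{**flash.__dict__, "phase": 0.5})
        trace = trace_factory(flash.flux_at(t), frame_rate=fps)
        events = segment_flashes(trace)
        events = [e for e in events if e.onset > t[0] and e.offset < t[-1]]
        s = summarize(events)
        truth = flash.truth_metrics()
        assert s.n_flashes >= 20
        assert s.mean_duration == pytest.approx(truth["duration"], abs=1 / fps)
        assert s.mean_peak_interval == pytest.approx(truth["peak_interval"], abs=1 / fps)
        if truth["subpulse_interval"] is not None:
            assert s.mean_subpulse_interval == pytest.approx(
                truth["subpulse_interval"], abs=1 / fps
            )
            assert all(n == truth["n_subpulses"] for n in s.pulses_per_flash)


class TestSummarize:
    def _event(self, onset, duration, peaks):
        return FlashEvent(onset, onset + duration, np.asarray(peaks), np.ones(len(peaks)))

    def test_single_peak_train_means(self):
        events = [self._event(p - 0.65, 1.3, [p]) for p in (0.65, 2.55, 4.45, 6.35)]
        s = summarize(events)
        assert s.n_flashes == 4
        assert s.mean_duration == pytest.approx(1.3)
        assert s.mean_peak_interval == pytest.approx(1.9)
        assert s.mean_interflash_interval == pytest.approx(0.6)
        assert s.mean_subpulse_interval is None

    def test_empty_event_list(self):
        s = summarize([])
        assert s.n_flashes == 0
        assert s.mean_duration is None
        assert s.mean_peak_interval is None

    def test_singleton_has_no_interval_means(self):
        s = summarize([self._event(0.0, 0.5, [0.2])])
        assert s.n_flashes == 1
        assert s.mean_duration == pytest.approx(0.5)
        assert s.mean_peak_interval is None
        assert s.mean_interflash_interval is None

    def test_subpulse_interval_mean(self):
        events = [
            self._event(0.0, 0.5, [0.1, 0.24]),
            self._event(1.0, 0.5, [1.1, 1.24]),
        ]
        assert summarize(events).mean_subpulse_interval == pytest.approx(0.14)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            FlashEvent(1.0, 0.5, np.array([0.7]), np.array([1.0]))
        with pytest.raises(ValueError):
            FlashEvent(0.0, 1.0, np.array([2.0]), np.array([1.0]))
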