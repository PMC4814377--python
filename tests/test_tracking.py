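import itertools

import numpy as np
import pytest

from flashtrace.tracking import (
    Detection,
    Roi,
    Track,
    detect_spots,
    link_tracks,
    load_manual_track,
    load_manual_tracks,
)


def gaussian_spot(shape, cx, cy, sigma=1.5, peak=200.0):
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return peak * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))


def brute_force_centroid(frame, threshold):
    """Independent oracle: brightness-weighted mean of above-threshold pixels."""
    ys, xs = np.nonzero(frame > threshold)
    w = frame[ys, xs]
    return (xs * w).sum() / w.sum(), (ys * w).sum() / w.sum()


class TestManualTrack:
    def _write(self, tmp_path, text):
        p = tmp_path / "trace.csv"
        p.write_text(text)
        return p

    def test_contiguous_rows(self, tmp_path):
        p = self._write(tmp_path, "frame,x,y\n0,10,10\n1,12,11\n2,14,12\n")
        t = load_manual_track(p, radius=5.0)
        assert len(t) == 3 and t.gaps == set()
        assert t.entries[1].center == (12.0, 11.0)
        assert t.radius == 5.0

    def test_missing_frame_becomes_interpolated_gap(self, tmp_path):
        p = self._write(tmp_path, "frame,x,y\n0,10,10\n2,14,12\n")
        t = load_manual_track(p, radius=5.0)
        assert t.gaps == {1}
        assert t.entries[1].center == (12.0, 11.0)  # linear midpoint

    def test_decreasing_frames_rejected(self, tmp_path):
        p = self._write(tmp_path, "frame,x,y\n1,10,10\n0,14,12\n")
        with pytest.raises(ValueError):
            load_manual_track(p, radius=5.0)

    def test_missing_column_rejected(self, tmp_path):
        p = self._write(tmp_path, "frame,x\n0,10\n")
        with pytest.raises(ValueError):
            load_manual_track(p, radius=5.0)

    def test_multi_individual_file(self, tmp_path):
        p = self._write(
            tmp_path,
            "frame,x,y,track_id\n0,1,1,0\n1,2,2,0\n0,9,9,1\n1,8,8,1\n",
        )
        tracks = load_manual_tracks(p, radius=3.0)
        assert [t.track_id for t in tracks] == [0, 1]
        assert all(len(t) == 2 for t in tracks)


class TestTrackInvariants:
    def test_radius_must_be_constant(self):
        with pytest.raises(ValueError):
            Track(0, [Roi((0, 0), 3, 0), Roi((1, 1), 4, 1)])

    def test_frames_must_be_contiguous(self):
        with pytest.raises(ValueError):
            Track(0, [Roi((0, 0), 3, 0), Roi((1, 1), 3, 2)])

    def test_roi_radius_floor(self):
        with pytest.raises(ValueError):
            Roi((0, 0), 0.5, 0)

    def test_extended_holds_boundary_centers(self):
        t = Track(0, [Roi((5.0, 5.0), 3, 2), Roi((6.0, 6.0), 3, 3)])
        e = t.extended(0, 5)
        assert e.first_frame == 0 and e.last_frame == 5
        assert e.entries[0].center == (5.0, 5.0)
        assert e.entries[-1].center == (6.0, 6.0)
        assert e.gaps == {0, 1, 4, 5}


class TestDetectSpots:
    def test_blank_frame(self):
        assert detect_spots(np.zeros((32, 32)), threshold=10) == []

    def test_single_spot_matches_weighted_centroid_oracle(self):
        frame = gaussian_spot((48, 48), cx=20.0, cy=30.0)
        dets = detect_spots(frame, threshold=50)
        assert len(dets) == 1
        ox, oy = brute_force_centroid(frame, 50)
        assert dets[0].centroid == pytest.approx((ox, oy), abs=1e-9)
        assert dets[0].centroid == pytest.approx((20.0, 30.0), abs=0.5)

    def test_two_spots_separate_detections(self):
        frame = gaussian_spot((64, 64), 15.0, 20.0) + gaussian_spot((64, 64), 35.0, 20.0, peak=150)
        dets = detect_spots(frame, threshold=50)
        assert len(dets) == 2
        # sorted by descending total brightness: the brighter spot first
        assert dets[0].total_brightness > dets[1].total_brightness
        assert dets[0].centroid[0] == pytest.approx(15.0, abs=0.5)

    def test_min_area_filters_specks(self):
        frame = np.zeros((16, 16))
        frame[4, 4] = 100.0
        assert detect_spots(frame, threshold=50, min_area=2) == []
        assert len(detect_spots(frame, threshold=50, min_area=1)) == 1


def exhaustive_link(centers_per_frame):
    """Oracle: per-frame minimum-total-displacement matching (equal counts,
    all tracks alive throughout)."""
    n = len(centers_per_frame[0])
    paths = [[c] for c in centers_per_frame[0]]
    for centers in centers_per_frame[1:]:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(n)):
            cost = sum(
                np.hypot(*(np.array(centers[perm[i]]) - np.array(paths[i][-1])))
                for i in range(n)
            )
            if cost < best_cost:
                best, best_cost = perm, cost
        for i in range(n):
            paths[i].append(centers[best[i]])
    return paths


def as_detections(centers_per_frame):
    return [
        [Detection((float(x), float(y)), 100.0, 5) for x, y in centers]
        for centers in centers_per_frame
    ]


class TestLinkTracks:
    def test_two_stationary_spots(self):
        frames = [[(10.0, 10.0), (40.0, 40.0)]] * 5
        tracks = link_tracks(as_detections(frames), max_jump=5)
        assert len(tracks) == 2
        assert all(len(t) == 5 and not t.gaps for t in tracks)

    def test_moving_spot_followed(self):
        frames = [[(10.0 + 2 * f, 20.0)] for f in range(8)]
        tracks = link_tracks(as_detections(frames), max_jump=5)
        assert len(tracks) == 1
        assert tracks[0].positions[:, 0] == pytest.approx(10 + 2 * np.arange(8))

    def test_teleport_splits_track(self):
        frames = [[(10.0 + 2 * f, 20.0)] for f in range(3)]
        frames += [[(80.0, 20.0)]] * 3
        tracks = link_tracks(as_detections(frames), max_jump=5, max_gap=0)
        assert len(tracks) == 2
        assert tracks[0].last_frame == 2
        assert tracks[1].first_frame == 3

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle_when_spots_well_separated(self, seed):
        # ≤3 spots, ≤10 frames, per-frame displacement ≤ 1.5 px and
        # inter-spot distance > 2×max displacement: greedy must equal the
        # exhaustive minimum-total-displacement assignment.
        rng = np.random.default_rng(seed)
        n_spots, n_frames = 3, 10
        base = np.array([[10.0, 10.0], [30.0, 30.0], [50.0, 10.0]])
        pos = [base + rng.uniform(-1, 1, size=base.shape)]
        for _ in range(n_frames - 1):
            pos.append(pos[-1] + rng.uniform(-1.5, 1.5, size=base.shape) / np.sqrt(2))
        centers = [[tuple(p) for p in frame] for frame in pos]
        tracks = link_tracks(as_detections(centers), max_jump=6)
        oracle = exhaustive_link(centers)
        assert len(tracks) == n_spots
        got = sorted(tuple(map(tuple, t.positions)) for t in tracks)
        want = sorted(tuple(map(tuple, path)) for path in oracle)
        assert got == want

    def test_deterministic(self, rng):
        centers = [
            [(float(x), float(y)) for x, y in rng.uniform(0, 60, size=(3, 2))]
            for _ in range(6)
        ]
        a = link_tracks(as_detections(centers), max_jump=50)
        b = link_tracks(as_detections(centers), max_jump=50)
        assert [(t.track_id, t.positions.tolist()) for t in a] == [
            (t.track_id, t.positions.tolist()) for t in b
        ]

    def test_min_obs_drops_blips(self):
        frames = [[(10.0, 10.0)]] * 6
        frames[3] = [(10.0, 10.0), (55.0, 55.0)]  # one-frame noise blip
        tracks = link_tracks(as_detections(frames), max_jump=5, min_obs=2)
        assert len(tracks) == 1


class TestSimulatedRecovery:
    def test_noncrossing_trajectories_recovered_within_2px(self):
        """Full detect→link on a rendered scene: ≥95% of positions within 2 px."""
        from flashtrace import make_scene
        from flashtrace.synthetic import FlashSpec, IndividualSpec, SceneSpec, TrajectorySpec
        from flashtrace.tracking import detect_spots

        individuals = tuple(
            IndividualSpec(
                TrajectorySpec("linear", start=(12.0, 12.0 + 19.0 * i), velocity=(0.9, 0.0)),
                FlashSpec("rectangular", flash_duration=1.0, period=1.0, amplitude=600.0),
            )
            for i in range(5)
        )
        spec = SceneSpec(
            individuals, duration=100 / 30.0, frame_rate=30.0, frame_size=(120, 140),
            noise_sigma=1.0, seed=7,
        )
        seq, truth = make_scene(spec)
        dets = [detect_spots(f, threshold=8.0) for f in seq.frames]
        tracks = link_tracks(dets, max_jump=6, roi_radius=5, min_obs=5)
        assert len(tracks) == 5
        n_ok = n_tot = 0
        for t in tracks:
            # match to the nearest truth individual at the first frame
            d0 = np.linalg.norm(truth.centers[:, t.first_frame] - t.positions[0], axis=1)
            i = int(np.argmin(d0))
            err = np.linalg.norm(
                truth.centers[i, t.first_frame : t.last_frame + 1] - t.positions, axis=1
            )
            n_ok += int((err <= 2.0).sum())
            n_tot += len(err)
        assert n_tot >= 5 * 90
        assert n_ok / n_tot >= 0.95
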