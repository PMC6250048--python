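import numpy as np
import pytest

from protonct.detector import PlaneGeometry, StripFrame, project_measurement
from protonct.range_telescope import RTTrack
from protonct.tracker import (
    TrackerPoint,
    TrackVector,
    default_triplet_planes,
    find_virtual_pixels,
    match_events,
    station_vector,
    xy_reference_candidates,
)

from oracles import enumerate_triples

PLANES = default_triplet_planes()
PITCH = PLANES[0].pitch


def digitize_points(points):
    """Strip frames of one station for a list of true (x, y) points."""
    frames = []
    for plane in PLANES:
        strips = []
        for x, y in points:
            m = project_measurement(np.array([x, y]), plane.axis_angle)
            strips.append(int(np.floor((m - plane.m_min) / plane.pitch)))
        frames.append(StripFrame(0, 0, np.unique(strips), np.zeros(len(set(strips)), bool)))
    return frames


class TestVirtualPixels:
    def test_single_proton_position(self):
        pts = find_virtual_pixels(digitize_points([(10.0, 20.0)]))
        assert len(pts) == 1
        assert np.linalg.norm(pts[0].xy - [10.0, 20.0]) <= PITCH / 2 * np.sqrt(2) + 1e-9
        assert pts[0].consistency_residual <= 1.5 * PITCH

    def test_matches_brute_force_enumeration(self, rng):
        truth = [(rng.uniform(-30, 30), rng.uniform(-30, 30)) for _ in range(3)]
        frames = digitize_points(truth)
        m = [PLANES[i].m_min + (frames[i].fired_strips + 0.5) * PITCH for i in range(3)]
        cands = enumerate_triples(m[0], m[1], m[2], 1.5 * PITCH)
        pts = find_virtual_pixels(frames)
        # greedy exclusive assignment returns a subset of the brute-force
        # candidate set, one per strip
        cand_xy = {(round(a, 3), round(y, 3)) for _, _, _, a, y in cands}
        for p in pts:
            assert (round(p.xy[0], 3), round(p.xy[1], 3)) in cand_xy
        assert len(pts) >= len(truth)  # every true proton recovered

    def test_ghost_rejection_two_protons(self):
        """Two protons on the x axis: an x-y system sees 4 candidates
        (2 ghosts); the third plane rejects both ghosts."""
        truth = [(-20.0, 0.0), (20.0, 0.0)]
        xy_cands = xy_reference_candidates([-20.0, 20.0], [0.0, 0.0])
        assert len(xy_cands) == 4
        pts = find_virtual_pixels(digitize_points(truth))
        assert len(pts) == 2
        got = sorted(round(p.xy[0]) for p in pts)
        assert got == [-20, 20]

    def test_two_planes_only_no_pixels(self):
        frames = digitize_points([(5.0, 5.0)])
        frames[2] = StripFrame(2, 0, np.array([], dtype=int), np.array([], dtype=bool))
        assert find_virtual_pixels(frames) == []

    def test_mismatched_frames_rejected(self):
        frames = digitize_points([(5.0, 5.0)])
        frames[1].frame_index = 99
        with pytest.raises(ValueError):
            find_virtual_pixels(frames)

    @pytest.mark.parametrize("k", [2, 3, 4, 6, 8])
    def test_ghost_rate_below_xy_reference(self, k, rng):
        """x-u-v ghost count stays below the k^2 - k of a two-plane x-y
        station at the same occupancy."""
        total_ghosts_xuv = 0
        total_ghosts_xy = 0
        for _ in range(30):
            truth = np.column_stack([rng.uniform(-35, 35, k), rng.uniform(-35, 35, k)])
            pts = find_virtual_pixels(digitize_points([tuple(t) for t in truth]))
            matched = 0
            used = set()
            for p in pts:
                d = np.linalg.norm(truth - p.xy, axis=1)
                i = int(np.argmin(d))
                if d[i] < 3 * PITCH and i not in used:
                    used.add(i)
                    matched += 1
            total_ghosts_xuv += len(pts) - matched
            total_ghosts_xy += k * k - k
        assert total_ghosts_xuv < total_ghosts_xy


class TestStationVector:
    def test_parallel_to_axis(self):
        p1 = TrackerPoint(0, np.array([3.0, 4.0]), 0, 0.0)
        p2 = TrackerPoint(1, np.array([3.0, 4.0]), 0, 0.0)
        v = station_vector(p1, p2, -180.0, -120.0)
        np.testing.assert_allclose(v.direction, [0, 0, 1])

    def test_oblique_direction(self):
        p1 = TrackerPoint(0, np.array([0.0, 0.0]), 0, 0.0)
        p2 = TrackerPoint(1, np.array([6.0, 0.0]), 0, 0.0)
        v = station_vector(p1, p2, 0.0, 60.0)
        expected = np.array([0.1, 0.0, 1.0])
        np.testing.assert_allclose(v.direction, expected / np.linalg.norm(expected))

    def test_mismatched_frames_error(self):
        p1 = TrackerPoint(0, np.zeros(2), 0, 0.0)
        p2 = TrackerPoint(1, np.zeros(2), 1, 0.0)
        with pytest.raises(ValueError):
            station_vector(p1, p2, 0.0, 60.0)

    def test_angle_error_bound_after_digitization(self, rng):
        """Round trip: digitized two-station vector within 3*atan(pitch/dz)
        of the true direction."""
        dz = 60.0
        bound = 3 * np.arctan(PITCH / dz)
        for _ in range(25):
            x0, y0 = rng.uniform(-30, 30, 2)
            sx, sy = rng.uniform(-0.05, 0.05, 2)
            pts = []
            for z in (0.0, dz):
                frames = digitize_points([(x0 + sx * z, y0 + sy * z)])
                pts.append(find_virtual_pixels(frames)[0])
            v = station_vector(pts[0], pts[1], 0.0, dz)
            true_d = np.array([sx, sy, 1.0])
            true_d /= np.linalg.norm(true_d)
            angle = np.arccos(np.clip(v.direction @ true_d, -1, 1))
            assert angle <= bound


def make_vector(x, y, frame, slope=(0.0, 0.0), z=-180.0):
    d = np.array([slope[0], slope[1], 1.0])
    return TrackVector(np.array([x, y, z]), d / np.linalg.norm(d), frame)


def make_rt_track(frame, x0=0.0, last=10, punch=False):
    return RTTrack(frame, [(0, x0)], last, punch_through=punch)


class TestMatchEvents:
    def test_single_proton_frames_fully_matched(self):
        ups = [make_vector(1.0, 2.0, f) for f in range(5)]
        downs = [make_vector(1.0, 2.0, f, z=120.0) for f in range(5)]
        rts = [make_rt_track(f) for f in range(5)]
        events, counters = match_events(ups, downs, rts)
        assert counters["matched"] == 5
        assert len(events) == 5

    def test_missing_rt_track_drops_event(self):
        ups = [make_vector(0.0, 0.0, 0)]
        downs = [make_vector(0.0, 0.0, 0, z=120.0)]
        events, counters = match_events(ups, downs, [])
        assert events == []
        assert counters["no_rt_track"] == 1

    def test_punch_through_rejected(self):
        ups = [make_vector(0.0, 0.0, 0)]
        downs = [make_vector(0.0, 0.0, 0, z=120.0)]
        rts = [make_rt_track(0, last=20, punch=True)]
        events, counters = match_events(ups, downs, rts)
        assert events == []
        assert counters["punch_through"] == 1

    def test_multi_proton_frame_true_pairing(self):
        """Four well-separated protons in one frame pair up correctly."""
        xs = [-30.0, -10.0, 10.0, 30.0]
        ups = [make_vector(x, 0.0, 0) for x in xs]
        downs = [make_vector(x + 0.5, 0.3, 0, z=120.0) for x in reversed(xs)]
        rts = [make_rt_track(0, x0=x) for x in xs]
        events, counters = match_events(ups, downs, rts)
        assert counters["matched"] == 4
        for e in events:
            assert abs(e.entry_point[0] - e.exit_point[0]) < 2.0
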