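"""Tracker reconstruction: virtual pixels, track vectors, event matching.

A station measures three 1-D coordinates (axes 0/60/120 deg).  For
continuous coordinates the three measurements obey ``m0 - m60 + m120 = 0``
exactly; after strip digitization the identity holds to pitch scale, so a
candidate (x-strip, u-strip, v-strip) triple is accepted as a *virtual
pixel* only if the third measurement agrees with the prediction from the
other two within a tolerance (default 1.5 x pitch).  This over-determination
is what rejects the combinatorial ghosts an x-y two-plane system cannot
distinguish at occupancies above one proton per readout cycle.

Two object-level code paths are provided: the per-frame combinatorial
reconstruction (any occupancy, greedy smallest-residual assignment,
lower strip index breaking ties) and a vectorised stream path for
single-occupancy frames used by the scan pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .detector import (
    RT_PLANE_ID_BASE,
    PlaneGeometry,
    RTGeometry,
    StripFrame,
    TrackerGeometry,
)

__all__ = [
    "TrackerPoint",
    "TrackVector",
    "ProtonEvent",
    "EventArrays",
    "find_virtual_pixels",
    "station_vector",
    "match_events",
    "xy_reference_candidates",
    "build_events_stream",
]

_SIN60 = np.sqrt(3.0) / 2.0


@dataclass
class TrackerPoint:
    station_id: int
    xy: np.ndarray
    frame_index: int
    consistency_residual: float


@dataclass
class TrackVector:
    """Ray through a station pair: ``point`` on the front reference plane,
    unit ``direction`` towards the back."""

    point: np.ndarray
    direction: np.ndarray
    frame_index: int

    def xy_at(self, z: float) -> np.ndarray:
        t = (z - self.point[2]) / self.direction[2]
        return self.point[:2] + t * self.direction[:2]


@dataclass
class ProtonEvent:
    """One reconstructed proton: entry/exit rays, RT stopping layer and
    (once calibrated) water-equivalent path length."""

    frame_index: int
    entry_point: np.ndarray
    entry_direction: np.ndarray
    exit_point: np.ndarray
    exit_direction: np.ndarray
    rt_last_layer: int
    punch_through: bool = False
    wepl: float = float("nan")


def _strip_centers(frame: StripFrame, plane: PlaneGeometry) -> np.ndarray:
    return plane.m_min + (frame.fired_strips + 0.5) * plane.pitch


def default_triplet_planes(pitch: float = 0.0908, n_strips: int = 2048):
    return [PlaneGeometry(0.0, a, n_strips, pitch) for a in (0.0, 60.0, 120.0)]


def find_virtual_pixels(
    frame_triplet,
    planes=None,
    tolerance: float | None = None,
) -> list[TrackerPoint]:
    """Virtual pixels from the three planes of one station in one frame.

    Enumerates all strip triples, solves (x, y) from the 0- and 60-degree
    measurements, accepts a triple iff the 120-degree measurement agrees
    within ``tolerance``, and assigns strips greedily by smallest
    consistency residual (each strip used at most once).
    """
    f0, f60, f120 = frame_triplet
    if not (f0.frame_index == f60.frame_index == f120.frame_index):
        raise ValueError("frames of a triplet must share frame_index")
    planes = planes or default_triplet_planes()
    if tolerance is None:
        tolerance = 1.5 * planes[0].pitch
    if min(len(f0.fired_strips), len(f60.fired_strips), len(f120.fired_strips)) == 0:
        return []
    m0 = _strip_centers(f0, planes[0])
    m60 = _strip_centers(f60, planes[1])
    m120 = _strip_centers(f120, planes[2])

    cands = []
    for (i, a), (j, b), (k, c) in product(
        enumerate(m0), enumerate(m60), enumerate(m120)
    ):
        residual = abs(a - b + c)
        if residual <= tolerance:
            cands.append((residual, i, j, k, a, b))
    cands.sort(key=lambda t: (t[0], t[1], t[2], t[3]))

    used0, used60, used120 = set(), set(), set()
    points = []
    station_id = int(f0.plane_id) // 3
    for residual, i, j, k, a, b in cands:
        if i in used0 or j in used60 or k in used120:
            continue
        used0.add(i)
        used60.add(j)
        used120.add(k)
        x = a
        y = (b - 0.5 * a) / _SIN60
        points.append(
            TrackerPoint(station_id, np.array([x, y]), f0.frame_index, residual)
        )
    return points


def station_vector(
    p_front: TrackerPoint, p_back: TrackerPoint, z_front: float, z_back: float
) -> TrackVector:
    """Ray through two station points (the entry or exit trajectory)."""
    if p_front.frame_index != p_back.frame_index:
        raise ValueError("pairing error: points from different frames")
    if z_back == z_front:
        raise ValueError("stations must be at distinct z")
    d = np.array(
        [p_back.xy[0] - p_front.xy[0], p_back.xy[1] - p_front.xy[1], z_back - z_front]
    )
    d = d / np.linalg.norm(d)
    point = np.array([p_front.xy[0], p_front.xy[1], z_front])
    return TrackVector(point, d, p_front.frame_index)


def match_events(
    upstream: list[TrackVector],
    downstream: list[TrackVector],
    rt_tracks,
    z_match: float = 0.0,
    gate: float = 5.0,
    rt_gate: float = 5.0,
    rt_layer0_z: float | None = None,
) -> tuple[list[ProtonEvent], dict]:
    """Pair upstream and downstream vectors frame by frame and link each
    pair to an RT track.

    Pairing is nearest-neighbour on lateral position extrapolated to the
    phantom mid-plane ``z_match``, with a ``gate`` (mm); unmatched vectors
    are dropped and counted, never raised.  RT tracks are linked by
    nearest first-layer position; punch-through tracks are rejected.
    """
    counters = {"matched": 0, "unmatched": 0, "no_rt_track": 0, "punch_through": 0}
    events: list[ProtonEvent] = []
    frames = sorted(
        {v.frame_index for v in upstream} | {v.frame_index for v in downstream}
    )
    rt_by_frame: dict[int, list] = {}
    for tr in rt_tracks:
        rt_by_frame.setdefault(tr.frame_index, []).append(tr)
    up_by_frame: dict[int, list] = {}
    for v in upstream:
        up_by_frame.setdefault(v.frame_index, []).append(v)
    down_by_frame: dict[int, list] = {}
    for v in downstream:
        down_by_frame.setdefault(v.frame_index, []).append(v)

    for fr in frames:
        ups = up_by_frame.get(fr, [])
        downs = down_by_frame.get(fr, [])
        rts = list(rt_by_frame.get(fr, []))
        if not ups or not downs:
            counters["unmatched"] += len(ups) + len(downs)
            continue
        pairs = []
        for iu, u in enumerate(ups):
            for idn, dn in enumerate(downs):
                dist = np.linalg.norm(u.xy_at(z_match) - dn.xy_at(z_match))
                if dist <= gate:
                    pairs.append((dist, iu, idn))
        pairs.sort()
        used_u, used_d = set(), set()
        for dist, iu, idn in pairs:
            if iu in used_u or idn in used_d:
                continue
            used_u.add(iu)
            used_d.add(idn)
            u, dn = ups[iu], downs[idn]
            # link an RT track: nearest first-layer x to the extrapolated ray
            best, best_dist = None, np.inf
            for tr in rts:
                if not tr.layer_hits:
                    continue
                layer0, x0 = tr.layer_hits[0]
                z0 = rt_layer0_z if rt_layer0_z is not None else None
                xpred = dn.xy_at(z0)[0] if z0 is not None else x0
                d_rt = abs(x0 - xpred)
                if d_rt < best_dist:
                    best, best_dist = tr, d_rt
            if best is None or best_dist > rt_gate:
                counters["no_rt_track"] += 1
                continue
            rts.remove(best)
            if best.punch_through:
                counters["punch_through"] += 1
                continue
            counters["matched"] += 1
            events.append(
                ProtonEvent(
                    frame_index=fr,
                    entry_point=u.point.copy(),
                    entry_direction=u.direction.copy(),
                    exit_point=dn.point.copy(),
                    exit_direction=dn.direction.copy(),
                    rt_last_layer=best.last_layer,
                    punch_through=best.punch_through,
                )
            )
        counters["unmatched"] += (len(ups) - len(used_u)) + (len(downs) - len(used_d))
    return events, counters


def xy_reference_candidates(xs, ys):
    """Candidate positions a two-plane x-y station would report for the
    same occupancy: every (x, y) combination is geometrically valid, so
    k protons produce k^2 candidates (k^2 - k ghosts).  Returned as an
    (k^2, 2) array; the reference for ghost-rate comparisons."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    return np.array([(x, y) for x in xs for y in ys])


# ---------------------------------------------------------------------------
# vectorised single-occupancy stream path


@dataclass
class EventArrays:
    """Column-oriented reconstructed events for one projection."""

    frame_index: np.ndarray
    entry_point: np.ndarray
    entry_direction: np.ndarray
    exit_point: np.ndarray
    exit_direction: np.ndarray
    rt_last_layer: np.ndarray
    wepl: np.ndarray
    proton: np.ndarray  # truth id (diagnostics only)

    def __len__(self) -> int:
        return self.frame_index.shape[0]


def _station_points_stream(table, geometry: TrackerGeometry, station: int,
                           tolerance: float, keep_proton: bool = False):
    """(frame_index, x, y[, proton]) for single-occupancy station frames."""
    dfs = []
    for a in range(3):
        pid = 3 * station + a
        plane = geometry.plane(pid)
        sel = table[table["plane_id"] == pid]
        m = plane.m_min + (sel["strip"].to_numpy() + 0.5) * plane.pitch
        cols = {"frame_index": sel["frame_index"].to_numpy(), f"m{a}": m}
        if a == 0 and keep_proton and "proton" in sel:
            cols["proton"] = sel["proton"].to_numpy()
        dfs.append(pd.DataFrame(cols).drop_duplicates("frame_index"))
    merged = dfs[0].merge(dfs[1], on="frame_index").merge(dfs[2], on="frame_index")
    residual = np.abs(merged["m0"] - merged["m1"] + merged["m2"])
    merged = merged[residual <= tolerance].copy()
    merged["x"] = merged["m0"]
    merged["y"] = (merged["m1"] - 0.5 * merged["m0"]) / _SIN60
    keep = ["frame_index", "x", "y"] + (["proton"] if "proton" in merged else [])
    return merged[keep]


def _rt_last_layer_stream(rt_table, rt: RTGeometry, window: float,
                          widen: float, max_gap: int):
    """Vectorised track-following for single-occupancy RT frames.

    Returns DataFrame (frame_index, last_layer, punch_through)."""
    frames = np.unique(rt_table["frame_index"])
    if frames.size == 0:
        return pd.DataFrame({"frame_index": [], "last_layer": [], "punch_through": []})
    pos = {f: i for i, f in enumerate(frames)}
    xmat = np.full((frames.size, rt.n_layers), np.nan)
    layer = rt_table["plane_id"].to_numpy() - RT_PLANE_ID_BASE
    row = np.vectorize(pos.get)(rt_table["frame_index"].to_numpy())
    plane0 = rt.plane(0)
    m = plane0.m_min + (rt_table["strip"].to_numpy() + 0.5) * plane0.pitch
    xmat[row, layer] = m

    has0 = np.isfinite(xmat[:, 0])
    last = np.full(frames.size, -1, dtype=np.int64)
    last[has0] = 0
    alive = has0.copy()
    gap = np.zeros(frames.size, dtype=np.int64)
    xref = xmat[:, 0].copy()
    for l in range(1, rt.n_layers):
        win = window + widen * l
        hit = alive & np.isfinite(xmat[:, l]) & (np.abs(xmat[:, l] - xref) <= win)
        miss = alive & ~hit
        gap[hit] = 0
        xref[hit] = xmat[hit, l]
        last[hit] = l
        gap[miss] += 1
        alive &= gap <= max_gap
    return pd.DataFrame(
        {
            "frame_index": frames,
            "last_layer": last,
            "punch_through": last >= rt.veto_layers[1],
        }
    )[last >= 0]


def build_events_stream(
    tracker_table: pd.DataFrame,
    rt_table: pd.DataFrame,
    geometry: TrackerGeometry,
    rt: RTGeometry,
    tolerance: float | None = None,
    gate: float = 5.0,
    rt_window: float = 2.0,
    rt_widen: float = 0.5,
    rt_max_gap: int = 1,
) -> tuple[EventArrays, dict]:
    """Full event reconstruction for a single-occupancy frame stream.

    Equivalent to find_virtual_pixels + station_vector + RT
    track-following + match_events at one proton per frame, but fully
    vectorised.  Returns events plus stage counters.
    """
    if tolerance is None:
        tolerance = 1.5 * geometry.pitch
    pts = [
        _station_points_stream(tracker_table, geometry, s, tolerance,
                               keep_proton=(s == 0))
        for s in range(4)
    ]
    counters: dict[str, int] = {}

    up = pts[0].merge(pts[1], on="frame_index", suffixes=("_a", "_b"))
    down = pts[2].merge(pts[3], on="frame_index", suffixes=("_a", "_b"))
    rt_last = _rt_last_layer_stream(rt_table, rt, rt_window, rt_widen, rt_max_gap)

    ev = up.merge(down, on="frame_index", suffixes=("_up", "_dn"))
    ev = ev.merge(rt_last, on="frame_index", how="left")
    counters["tracker_complete"] = len(ev)

    z = geometry.station_z
    dz_up = z[1] - z[0]
    dz_dn = z[3] - z[2]

    def ray(df, xa, ya, xb, yb, z_front, dz):
        p = np.column_stack(
            [df[xa].to_numpy(), df[ya].to_numpy(), np.full(len(df), z_front)]
        )
        d = np.column_stack(
            [
                df[xb].to_numpy() - df[xa].to_numpy(),
                df[yb].to_numpy() - df[ya].to_numpy(),
                np.full(len(df), dz),
            ]
        )
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return p, d

    p_in, d_in = ray(ev, "x_a_up", "y_a_up", "x_b_up", "y_b_up", z[0], dz_up)
    p_out, d_out = ray(ev, "x_a_dn", "y_a_dn", "x_b_dn", "y_b_dn", z[2], dz_dn)

    # mid-plane gate (z = 0)
    t_in = (0.0 - p_in[:, 2]) / d_in[:, 2]
    xy_mid_in = p_in[:, :2] + t_in[:, None] * d_in[:, :2]
    t_out = (0.0 - p_out[:, 2]) / d_out[:, 2]
    xy_mid_out = p_out[:, :2] + t_out[:, None] * d_out[:, :2]
    gate_ok = np.linalg.norm(xy_mid_in - xy_mid_out, axis=1) <= gate

    has_rt = ev["last_layer"].notna().to_numpy()
    punch = np.zeros(len(ev), dtype=bool)
    punch[has_rt] = ev.loc[has_rt, "punch_through"].to_numpy().astype(bool)
    good = gate_ok & has_rt & ~punch
    counters["gate_rejected"] = int(np.sum(~gate_ok))
    counters["no_rt_track"] = int(np.sum(gate_ok & ~has_rt))
    counters["punch_through"] = int(np.sum(gate_ok & has_rt & punch))
    counters["matched"] = int(np.sum(good))

    proton = (
        ev["proton"].to_numpy() if "proton" in ev else ev["frame_index"].to_numpy()
    )
    events = EventArrays(
        frame_index=ev["frame_index"].to_numpy()[good],
        entry_point=p_in[good],
        entry_direction=d_in[good],
        exit_point=p_out[good],
        exit_direction=d_out[good],
        rt_last_layer=ev["last_layer"].to_numpy()[good].astype(np.int64),
        wepl=np.full(int(np.sum(good)), np.nan),
        proton=proton[good],
    )
    return events, counters
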