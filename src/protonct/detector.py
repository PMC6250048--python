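"""Silicon-strip detector model: geometry and digitization.

Tracker stations hold three strip planes in the x-u-v arrangement
(axes 0/60/120 degrees); the range telescope (RT) is a stack of 21
one-dimensional strip layers interleaved with PMMA absorbers, 2.6 mm of
water-equivalent thickness per layer.  Digitization maps a true crossing
point to the strip whose half-open bin ``[m_min + i*pitch,
m_min + (i+1)*pitch)`` contains the projected measurement, applies a
Bernoulli detection efficiency (strip detectors are better than 99%
efficient), and groups protons into readout frames of the 26 MHz clock.
Two protons landing on the same strip of one plane in one frame collapse
to a single fired strip with the high-threshold (double-hit) flag set.

Hit streams are columnar tables (pandas) with columns
``plane_id, frame_index, strip, high_flag`` plus a ``proton`` truth
column used only by tests and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import MATERIALS, energy_from_range, highland_sigma
from .transport import HistoryBatch, NUCLEAR_LOSS_PER_WE_MM

__all__ = [
    "READOUT_MHZ",
    "MAX_CHANNELS_PER_CYCLE",
    "PlaneGeometry",
    "TrackerGeometry",
    "RTGeometry",
    "StripFrame",
    "project_measurement",
    "digitize_crossing",
    "digitize_tracker",
    "rt_crossings",
    "digitize_rt",
    "assemble_frames",
    "frames_from_table",
]

READOUT_MHZ = 26.0
MAX_CHANNELS_PER_CYCLE = 8
DETECTION_EFFICIENCY = 0.99

RT_PLANE_ID_BASE = 100  # plane_id = RT_PLANE_ID_BASE + layer


@dataclass(frozen=True)
class PlaneGeometry:
    """One strip plane.  ``axis_angle`` is the strip-measurement axis in
    degrees (0 measures x, 60 and 120 the rotated coordinates)."""

    z_position: float
    axis_angle: float
    n_strips: int = 2048
    pitch: float = 0.0908
    thickness: float = 0.150

    @property
    def active_extent(self) -> float:
        return self.n_strips * self.pitch

    @property
    def m_min(self) -> float:
        return -self.active_extent / 2.0


@dataclass(frozen=True)
class TrackerGeometry:
    """Four x-u-v stations: two upstream, two downstream of the phantom.

    Station reference z positions default to -180/-120/+120/+180 mm with
    the three planes of a station spaced ``plane_gap`` apart.  Plane ids
    are ``3 * station + axis_index``.
    """

    station_z: tuple[float, ...] = (-180.0, -120.0, 120.0, 180.0)
    plane_gap: float = 2.0
    axis_angles: tuple[float, ...] = (0.0, 60.0, 120.0)
    n_strips: int = 2048
    pitch: float = 0.0908

    def planes(self) -> list[PlaneGeometry]:
        out = []
        for s, z0 in enumerate(self.station_z):
            for a, angle in enumerate(self.axis_angles):
                out.append(
                    PlaneGeometry(z0 + a * self.plane_gap, angle,
                                  self.n_strips, self.pitch)
                )
        return out

    def plane(self, plane_id: int) -> PlaneGeometry:
        return self.planes()[plane_id]


@dataclass(frozen=True)
class RTGeometry:
    """Range telescope: 21 strip layers, 2.6 mm WET per layer.

    ``total_wet_printed`` stores the instrument's quoted overall WET
    independently of ``n_layers * wet_per_layer`` (the two disagree by
    0.8 mm); the calibration is anchored to the per-layer WET.
    """

    n_layers: int = 21
    wet_per_layer: float = 2.6
    absorber_thickness: float = 2.0
    z_first: float = 200.0
    layer_spacing: float = 4.0
    n_strips: int = 2048
    pitch: float = 0.0908
    total_wet_printed: float = 55.4
    veto_layers: tuple[int, int] = (0, 20)

    def __post_init__(self) -> None:
        if self.n_layers < 2 or self.wet_per_layer <= 0:
            raise ValueError("invalid RT geometry")

    @property
    def layer_z(self) -> np.ndarray:
        return self.z_first + self.layer_spacing * np.arange(self.n_layers)

    @property
    def total_wet(self) -> float:
        return self.n_layers * self.wet_per_layer

    def plane(self, layer: int) -> PlaneGeometry:
        return PlaneGeometry(float(self.layer_z[layer]), 0.0,
                             self.n_strips, self.pitch)


@dataclass
class StripFrame:
    """One readout cycle of one plane."""

    plane_id: int
    frame_index: int
    fired_strips: np.ndarray
    high_threshold_flags: np.ndarray

    def __post_init__(self) -> None:
        self.fired_strips = np.asarray(self.fired_strips, dtype=np.int64)
        self.high_threshold_flags = np.asarray(self.high_threshold_flags, dtype=bool)


def project_measurement(point_xy, axis_angle: float):
    """Strip-axis measurement ``m = x cos(theta) + y sin(theta)`` (mm)."""
    p = np.asarray(point_xy, float)
    th = np.deg2rad(axis_angle)
    return p[..., 0] * np.cos(th) + p[..., 1] * np.sin(th)


def _strip_index(m, plane: PlaneGeometry):
    """Half-open binning; -1 marks a miss (outside the active area)."""
    m = np.asarray(m, float)
    idx = np.floor((m - plane.m_min) / plane.pitch)
    miss = (idx < 0) | (idx >= plane.n_strips) | ~np.isfinite(m)
    return np.where(miss, -1, idx).astype(np.int64)


def digitize_crossing(history, plane: PlaneGeometry, rng: np.random.Generator,
                      efficiency: float = DETECTION_EFFICIENCY):
    """Digitize one proton crossing of one plane: the strip index, or
    ``None`` on a geometric miss or detection inefficiency.

    The entry ray is used for upstream planes (z < 0), the exit ray for
    downstream planes.
    """
    if plane.z_position < 0:
        pos, d = history.entry_pos, history.entry_dir
    else:
        pos, d = history.exit_pos, history.exit_dir
    if not np.all(np.isfinite(pos)):
        return None
    t = (plane.z_position - pos[2]) / d[2]
    xy = pos[:2] + t * d[:2]
    m = project_measurement(xy, plane.axis_angle)
    idx = int(_strip_index(np.array([m]), plane)[0])
    if idx < 0 or rng.random() >= efficiency:
        return None
    return idx


def digitize_tracker(
    batch: HistoryBatch,
    geometry: TrackerGeometry,
    rng: np.random.Generator,
    efficiency: float = DETECTION_EFFICIENCY,
) -> pd.DataFrame:
    """Digitize all tracker planes for a history batch (vectorised).

    Upstream planes fire for every proton whose entry state is defined
    (a proton later stopping in the phantom still crossed the proximal
    tracker); downstream planes only for protons that reached the exit
    reference plane.
    """
    recs = []
    for pid, plane in enumerate(geometry.planes()):
        if plane.z_position < 0:
            pos, d = batch.entry_pos, batch.entry_dir
        else:
            pos, d = batch.exit_pos, batch.exit_dir
        valid = np.isfinite(pos[:, 2]) & (d[:, 2] > 1e-9)
        idxv = np.flatnonzero(valid)
        t = (plane.z_position - pos[idxv, 2]) / d[idxv, 2]
        xy = pos[idxv, :2] + t[:, None] * d[idxv, :2]
        m = xy[:, 0] * np.cos(np.deg2rad(plane.axis_angle)) + \
            xy[:, 1] * np.sin(np.deg2rad(plane.axis_angle))
        strip = _strip_index(m, plane)
        keep = (strip >= 0) & (rng.random(idxv.size) < efficiency)
        recs.append(pd.DataFrame({
            "plane_id": np.int16(pid),
            "proton": idxv[keep],
            "strip": strip[keep],
        }))
    return pd.concat(recs, ignore_index=True)


def rt_crossings(
    batch: HistoryBatch,
    rt: RTGeometry,
    rng: np.random.Generator,
    scattering: bool = True,
    nuclear: bool = True,
) -> dict:
    """Propagate exiting protons through the RT stack.

    Layer ``i`` is reached once ``i * wet_per_layer`` of water-equivalent
    material has been crossed, so the deepest layer fired is
    ``floor(residual_range / wet_per_layer)`` (capped at the last layer).
    Scattering kicks accumulate between layers; nuclear attenuation can
    terminate a track early.  Returns per-proton layer x positions
    (n, n_layers), the fired mask, and the true stopping layer (-1 for
    protons that never reached the RT).
    """
    n = len(batch)
    x = np.full((n, rt.n_layers), np.nan)
    fired = np.zeros((n, rt.n_layers), dtype=bool)
    alive = batch.alive & np.isfinite(batch.exit_pos[:, 2])
    residual = batch.residual_range.copy()
    true_last = np.where(
        alive,
        np.minimum(np.floor(residual / rt.wet_per_layer), rt.n_layers - 1),
        -1,
    ).astype(np.int64)
    true_last[alive & (residual <= 0)] = -1

    pos = batch.exit_pos.copy()
    dirn = batch.exit_dir.copy()
    pmma = MATERIALS["pmma"]
    cur = alive.copy()
    for layer in range(rt.n_layers):
        cur &= true_last >= layer
        idx = np.flatnonzero(cur)
        if idx.size == 0:
            break
        zl = rt.layer_z[layer]
        t = (zl - pos[idx, 2]) / dirn[idx, 2]
        pos[idx] += t[:, None] * dirn[idx]
        x[idx, layer] = pos[idx, 0]
        fired[idx, layer] = True
        if nuclear:
            u = rng.random(idx.size)
            killed = u < NUCLEAR_LOSS_PER_WE_MM * rt.wet_per_layer
            true_last[idx[killed]] = layer
            cur[idx[killed]] = False
        if scattering:
            idx = np.flatnonzero(cur)
            if idx.size:
                rem = np.clip(residual[idx] - layer * rt.wet_per_layer, 0.5, None)
                energy = np.clip(energy_from_range(rem), 2.0, None)
                step_geom = rt.wet_per_layer / pmma.rsp
                sigma = highland_sigma(energy, step_geom, pmma)
                kick = rng.normal(0.0, sigma)
                dirn[idx, 0] += kick * dirn[idx, 2]
                dirn[idx] /= np.linalg.norm(dirn[idx], axis=1, keepdims=True)
    return {"x": x, "fired": fired, "true_last": true_last}


def digitize_rt(
    crossings: dict,
    rt: RTGeometry,
    rng: np.random.Generator,
    efficiency: float = DETECTION_EFFICIENCY,
) -> pd.DataFrame:
    """Digitize RT layer crossings into strip hits (1-D planes)."""
    recs = []
    for layer in range(rt.n_layers):
        plane = rt.plane(layer)
        m = crossings["x"][:, layer]
        valid = np.flatnonzero(crossings["fired"][:, layer])
        strip = _strip_index(m[valid], plane)
        keep = (strip >= 0) & (rng.random(valid.size) < efficiency)
        recs.append(pd.DataFrame({
            "plane_id": np.int16(RT_PLANE_ID_BASE + layer),
            "proton": valid[keep],
            "strip": strip[keep],
        }))
    return pd.concat(recs, ignore_index=True)


def assemble_frames(
    hits: pd.DataFrame,
    protons_per_frame: int,
    n_protons: int | None = None,
) -> pd.DataFrame:
    """Group per-proton hits into readout frames.

    ``frame_index = proton // protons_per_frame``: every plane crossed by
    one proton shares its frame.  Within a (plane, frame), hits on the
    same strip collapse to one fired strip with the high-threshold flag
    set (double-hit detection).  Frames exceeding the 8-channels-per-cycle
    budget on any plane are listed in ``result.attrs['channel_limit_frames']``.
    """
    if protons_per_frame < 1:
        raise ValueError("protons_per_frame must be >= 1")
    df = hits.copy()
    df["frame_index"] = (df["proton"] // protons_per_frame).astype(np.int64)
    grouped = (
        df.groupby(["plane_id", "frame_index", "strip"], sort=True)
        .agg(n=("proton", "size"), proton=("proton", "min"))
        .reset_index()
    )
    grouped["high_flag"] = grouped["n"] > 1
    grouped = grouped.drop(columns="n")
    per_plane = grouped.groupby(["plane_id", "frame_index"]).size()
    over = per_plane[per_plane > MAX_CHANNELS_PER_CYCLE]
    out = grouped[["plane_id", "frame_index", "strip", "high_flag", "proton"]]
    out.attrs["channel_limit_frames"] = np.unique(
        over.index.get_level_values("frame_index")
    )
    if n_protons is not None:
        out.attrs["n_frames"] = int(np.ceil(n_protons / protons_per_frame))
    return out


def frames_from_table(table: pd.DataFrame, plane_id: int, frame_index: int) -> StripFrame:
    """Extract one :class:`StripFrame` from a framed hit table."""
    sel = table[(table["plane_id"] == plane_id) & (table["frame_index"] == frame_index)]
    return StripFrame(
        plane_id=plane_id,
        frame_index=frame_index,
        fired_strips=sel["strip"].to_numpy(),
        high_threshold_flags=sel["high_flag"].to_numpy()
        if "high_flag" in sel
        else np.zeros(len(sel), dtype=bool),
    )
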