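"""Range-telescope reconstruction, WEPL calibration and the range budget.

A proton entering the telescope fires successive strip layers until its
residual range is exhausted; the deepest layer reached is its range
measurement.  Two uncertainty terms govern the WEPL resolution: range
straggling, sigma_s ~ 0.011 x R_tot, and the layer quantization term
sigma_w = WET_layer / sqrt(12) (uniform stopping position within a
layer); they add in quadrature.

Calibration maps stopping layer to residual water-equivalent range using
no-phantom runs at stepped degrader thicknesses: each degrader setting
has a known residual range at the telescope entrance and a measured modal
stopping layer; monotone interpolation inverts that relation for all 21
layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import RTGeometry, StripFrame
from .materials import water_range

__all__ = [
    "RTTrack",
    "CalibrationTable",
    "RangeBudget",
    "PunchThroughError",
    "CalibrationError",
    "follow_rt_tracks",
    "assign_wepl",
    "assign_wepl_array",
    "range_uncertainty",
    "fluence_depth_curve",
    "extract_range",
    "build_calibration",
]


class PunchThroughError(ValueError):
    """Raised when a WEPL is requested for a vetoed (punch-through) track."""


class CalibrationError(ValueError):
    """Raised when layer-vs-WET calibration data are not monotone."""


@dataclass
class RTTrack:
    frame_index: int
    layer_hits: list  # [(layer, x_mm), ...] contiguous from the seed layer
    last_layer: int
    punch_through: bool = False
    displacement_ok: bool = True


@dataclass
class RangeBudget:
    """sigma_total^2 = sigma_straggle^2 + sigma_layer^2 (exact)."""

    sigma_straggle: float
    sigma_layer: float
    sigma_total: float
    fraction_of_range: float


@dataclass
class CalibrationTable:
    """Per-layer residual water-equivalent range at the RT entrance (mm),
    strictly increasing with layer index."""

    residual_wet: np.ndarray
    beam_energy: float
    upstream_wet: float = 0.0

    def __post_init__(self) -> None:
        self.residual_wet = np.asarray(self.residual_wet, float)
        if np.any(np.diff(self.residual_wet) <= 0):
            raise CalibrationError("residual WET must increase strictly with layer")

    def residual(self, layer) -> np.ndarray:
        return self.residual_wet[np.asarray(layer, dtype=np.int64)]


def follow_rt_tracks(
    layer_frames: list[StripFrame],
    rt: RTGeometry,
    window: float = 2.0,
    widen: float = 0.5,
    max_gap: int = 1,
) -> list[RTTrack]:
    """Track-following through the RT stack for one readout frame.

    Seeds on first-layer hits, extends layer by layer accepting the
    nearest unused hit within a displacement window (which widens with
    depth to follow the growing scattering cone); a track ends after
    ``max_gap + 1`` consecutive layers without an acceptable hit.  Hits
    are consumed exclusively, so several disjoint tracks per frame are
    reconstructed.
    """
    if not layer_frames:
        return []
    frame_index = layer_frames[0].frame_index
    plane0 = rt.plane(0)
    hits = []
    for lf in layer_frames:
        xs = plane0.m_min + (np.asarray(lf.fired_strips, float) + 0.5) * plane0.pitch
        hits.append(list(xs))
    while len(hits) < rt.n_layers:
        hits.append([])

    tracks = []
    for seed_x in sorted(hits[0]):
        track = {"xs": [(0, seed_x)], "x_ref": seed_x, "gap": 0, "alive": True}
        tracks.append(track)
    hits[0] = []

    for layer in range(1, rt.n_layers):
        win = window + widen * layer
        # nearest-first assignment of this layer's hits to live tracks
        cands = []
        for it, tr in enumerate(tracks):
            if not tr["alive"]:
                continue
            for ih, x in enumerate(hits[layer]):
                d = abs(x - tr["x_ref"])
                if d <= win:
                    cands.append((d, it, ih))
        cands.sort()
        used_t, used_h = set(), set()
        for d, it, ih in cands:
            if it in used_t or ih in used_h:
                continue
            used_t.add(it)
            used_h.add(ih)
            tr = tracks[it]
            x = hits[layer][ih]
            tr["xs"].append((layer, x))
            tr["x_ref"] = x
            tr["gap"] = 0
        for it, tr in enumerate(tracks):
            if tr["alive"] and it not in used_t:
                tr["gap"] += 1
                if tr["gap"] > max_gap:
                    tr["alive"] = False
        hits[layer] = [x for i, x in enumerate(hits[layer]) if i not in used_h]

    out = []
    for tr in tracks:
        last = tr["xs"][-1][0]
        out.append(
            RTTrack(
                frame_index=frame_index,
                layer_hits=tr["xs"],
                last_layer=last,
                punch_through=last >= rt.veto_layers[1],
            )
        )
    return out


def range_uncertainty(total_range: float, wet_layer: float) -> RangeBudget:
    """Analytic range-uncertainty budget for a beam of CSDA range
    ``total_range`` measured with layers of ``wet_layer`` WET."""
    if total_range <= 0:
        raise ValueError("total_range must be positive")
    if wet_layer < 0:
        raise ValueError("wet_layer must be non-negative")
    sigma_s = 0.011 * total_range
    sigma_w = wet_layer / np.sqrt(12.0)
    sigma_t = float(np.hypot(sigma_s, sigma_w))
    return RangeBudget(
        sigma_straggle=sigma_s,
        sigma_layer=sigma_w,
        sigma_total=sigma_t,
        fraction_of_range=100.0 * sigma_t / total_range,
    )


def fluence_depth_curve(tracks) -> np.ndarray:
    """Normalised surviving-fluence curve: ``counts[L]`` = fraction of
    tracks whose stopping layer is >= L, normalised to the first layer.
    Monotonically non-increasing by construction."""
    if isinstance(tracks, np.ndarray) or (
        len(tracks) and not isinstance(tracks[0], RTTrack)
    ):
        last = np.asarray(tracks, dtype=np.int64)
    else:
        last = np.array([t.last_layer for t in tracks], dtype=np.int64)
    last = last[last >= 0]
    if last.size == 0:
        raise ValueError("no tracks")
    n_layers = int(last.max()) + 1
    counts = np.array([(last >= l).sum() for l in range(n_layers)], dtype=float)
    return counts / counts[0]


def extract_range(curve: np.ndarray) -> float:
    """Range in layer units: the (interpolated) layer where the curve
    falls below 50% of the first-layer plateau."""
    curve = np.asarray(curve, float)
    thresh = 0.5 * curve[0]
    below = np.flatnonzero(curve < thresh)
    if below.size == 0:
        return float(len(curve) - 1)
    l1 = below[0]
    if l1 == 0:
        return 0.0
    c0, c1 = curve[l1 - 1], curve[l1]
    return float(l1 - 1 + (c0 - thresh) / (c0 - c1))


def build_calibration(
    settings,
    beam_energy: float,
    rt: RTGeometry,
    upstream_wet: float = 0.0,
) -> CalibrationTable:
    """Build the layer -> residual-WET table from degrader runs.

    ``settings`` is a sequence of ``(degrader_wet_mm, stopping_layers)``
    pairs from no-phantom runs.  For each setting the modal stopping
    layer is paired with the known residual range ``R(E0) - w``; modal
    layers must decrease with degrader WET (monotonicity), and the pairs
    are interpolated (linearly, with WET-per-layer extrapolation at the
    ends) to all layers.
    """
    if len(settings) < 2:
        raise CalibrationError("need at least two degrader settings")
    r_beam = water_range(beam_energy)
    by_layer: dict[int, list[float]] = {}
    order_check = []
    for w, layers in settings:
        layers = np.asarray(layers)
        layers = layers[layers >= 0]
        if layers.size == 0:
            continue
        mode = int(np.bincount(layers.astype(np.int64)).argmax())
        if mode <= rt.veto_layers[0] or mode >= rt.veto_layers[1]:
            # the modal bin is truncated by a veto layer; its residual
            # range cannot be attributed to a layer centre
            continue
        order_check.append((w, mode))
        by_layer.setdefault(mode, []).append(r_beam - w - upstream_wet)
    order_check.sort()
    modes = [m for _, m in order_check]
    if any(m2 > m1 for (m1, m2) in zip(modes, modes[1:])):
        raise CalibrationError("stopping layer must not increase with degrader WET")
    known_layers = np.array(sorted(by_layer))
    known_r = np.array([np.mean(by_layer[l]) for l in known_layers])
    if known_layers.size < 2 or np.any(np.diff(known_r) <= 0):
        raise CalibrationError("degrader data do not give a monotone calibration")
    layers = np.arange(rt.n_layers)
    resid = np.interp(layers, known_layers, known_r)
    # linear extrapolation beyond the measured span at one WET per layer
    lo, hi = known_layers[0], known_layers[-1]
    below = layers < lo
    above = layers > hi
    resid[below] = known_r[0] - rt.wet_per_layer * (lo - layers[below])
    resid[above] = known_r[-1] + rt.wet_per_layer * (layers[above] - hi)
    if resid[0] <= 0:
        # keep the table positive and strictly increasing at the shallow end
        resid = resid - resid[0] + 0.1
    return CalibrationTable(resid, beam_energy, upstream_wet)


def assign_wepl(track: RTTrack, calib: CalibrationTable) -> float:
    """Calibrated WEPL of one track: beam range minus upstream WET minus
    the residual range of the stopping layer (clipped at zero)."""
    if track.punch_through:
        raise PunchThroughError("punch-through track has no range measurement")
    return float(assign_wepl_array(np.array([track.last_layer]), calib)[0])


def assign_wepl_array(last_layers, calib: CalibrationTable) -> np.ndarray:
    wepl = (
        water_range(calib.beam_energy)
        - calib.upstream_wet
        - calib.residual(last_layers)
    )
    return np.clip(wepl, 0.0, None)
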