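"""Per-proton Monte Carlo transport through compensator and phantom.

This is the package's synthetic-data generator.  Physics model:

* continuous slowing-down: each proton carries a water-equivalent range
  budget; every geometric step of length ``ds`` through material of
  relative stopping power ``rsp`` consumes ``rsp * ds`` of it;
* range straggling: the budget is drawn once per proton as
  ``R0 * (1 + 0.011 * Z)`` with ``Z`` standard normal, so protons that
  stop after consuming their full range exhibit the 1.1%-of-range spread;
* multiple Coulomb scattering: independent Highland-sigma angular kicks
  in the two transverse directions per material step;
* nuclear attenuation: protons are removed with probability 1% per cm of
  water-equivalent depth (inelastic collisions); secondaries are not
  simulated.

Transport is vectorised over protons; :func:`transport_history` is the
single-proton convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import (
    Material,
    energy_from_range,
    highland_sigma,
    water_range,
)
from .phantom import Compensator, PhantomModel, compensator_contains, rsp_at

__all__ = [
    "BeamSpec",
    "ProtonHistory",
    "HistoryBatch",
    "TransportOptions",
    "transport_beam",
    "transport_history",
]

#: nuclear removal probability per mm of water-equivalent depth
NUCLEAR_LOSS_PER_WE_MM = 0.001


@dataclass(frozen=True)
class BeamSpec:
    """Parallel proton beam along +z filling a circular field."""

    energy: float = 125.0
    field_diameter: float = 85.0
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    fluence_per_projection: int = 20000

    def __post_init__(self) -> None:
        if not (1.0 < self.energy < 300.0):
            raise ValueError("beam energy must be in (1, 300) MeV")
        if self.field_diameter <= 0:
            raise ValueError("field diameter must be positive")


@dataclass
class TransportOptions:
    """Physics switches and the geometric step length (mm)."""

    step: float = 1.0
    scattering: bool = True
    straggling: bool = True
    nuclear: bool = True


@dataclass
class ProtonHistory:
    """Ground truth for one simulated proton at the tracker reference
    planes.  ``true_wepl`` is the line integral of RSP along the actual
    (scattered) path."""

    entry_pos: np.ndarray
    entry_dir: np.ndarray
    exit_pos: np.ndarray
    exit_dir: np.ndarray
    energy_in: float
    energy_out: float
    true_wepl: float
    stopped_in_phantom: bool = False
    nuclear_loss: bool = False
    timestamp: int = 0


@dataclass
class HistoryBatch:
    """Structure-of-arrays container for many proton histories."""

    entry_pos: np.ndarray  # (n, 3) at the entry reference plane
    entry_dir: np.ndarray  # (n, 3) unit
    exit_pos: np.ndarray   # (n, 3) at the exit reference plane
    exit_dir: np.ndarray   # (n, 3) unit
    energy_in: np.ndarray
    energy_out: np.ndarray
    true_wepl: np.ndarray
    residual_range: np.ndarray  # straggled water-equivalent range left at exit
    stopped_in_phantom: np.ndarray
    nuclear_loss: np.ndarray
    timestamp: np.ndarray

    def __len__(self) -> int:
        return self.energy_in.shape[0]

    @property
    def alive(self) -> np.ndarray:
        """Protons that reached the exit reference plane."""
        return ~(self.stopped_in_phantom | self.nuclear_loss)

    def history(self, i: int) -> ProtonHistory:
        return ProtonHistory(
            entry_pos=self.entry_pos[i].copy(),
            entry_dir=self.entry_dir[i].copy(),
            exit_pos=self.exit_pos[i].copy(),
            exit_dir=self.exit_dir[i].copy(),
            energy_in=float(self.energy_in[i]),
            energy_out=float(self.energy_out[i]),
            true_wepl=float(self.true_wepl[i]),
            stopped_in_phantom=bool(self.stopped_in_phantom[i]),
            nuclear_loss=bool(self.nuclear_loss[i]),
            timestamp=int(self.timestamp[i]),
        )


def _transverse_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal transverse vectors for each direction in d (n,3)."""
    ref = np.zeros_like(d)
    ref[:, 0] = 1.0
    near_x = np.abs(d[:, 0]) > 0.9
    ref[near_x] = [0.0, 1.0, 0.0]
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    return e1, e2


def _scatter(d, energy, step_mm, material: Material, rng) -> np.ndarray:
    sigma = highland_sigma(np.clip(energy, 2.0, None), step_mm, material)
    e1, e2 = _transverse_basis(d)
    t1 = rng.normal(0.0, sigma)
    t2 = rng.normal(0.0, sigma)
    d_new = d + t1[:, None] * e1 + t2[:, None] * e2
    return d_new / np.linalg.norm(d_new, axis=1, keepdims=True)


def _step_zone(
    pos, dirn, wepl, w_stop, active, stopped, lost,
    z_end, rsp_lookup, scatter_material, r0, opts: TransportOptions, rng,
):
    """Advance all active protons through a material zone ending at z_end."""
    while True:
        moving = active & (pos[:, 2] < z_end) & ~stopped & ~lost
        if not np.any(moving):
            break
        idx = np.flatnonzero(moving)
        ds = opts.step
        # jittered sampling point: unbiased for material slivers thinner
        # than the step (midpoint sampling would alias shape boundaries)
        u = rng.random(idx.size)
        mid = pos[idx] + u[:, None] * ds * dirn[idx]
        rsp = rsp_lookup(mid)
        dw = rsp * ds
        new_w = wepl[idx] + dw
        # stop where the straggled range budget is exhausted
        exhausted = new_w >= w_stop[idx]
        wepl[idx] = np.minimum(new_w, w_stop[idx])
        stopped[idx[exhausted]] = True
        if opts.nuclear:
            u = rng.random(idx.size)
            lost_now = (~exhausted) & (u < NUCLEAR_LOSS_PER_WE_MM * dw)
            lost[idx[lost_now]] = True
        if opts.scattering:
            in_mat = rsp > 0
            sub = idx[in_mat]
            if sub.size:
                energy = energy_from_range(np.clip(r0[sub] - wepl[sub], 0.5, None))
                dirn[sub] = _scatter(dirn[sub], energy, ds, scatter_material, rng)
        adv = idx[~exhausted]
        pos[adv] += ds * dirn[adv]


def _propagate_to_plane(pos, dirn, mask, z_plane):
    idx = np.flatnonzero(mask & (dirn[:, 2] > 1e-9))
    t = (z_plane - pos[idx, 2]) / dirn[idx, 2]
    pos[idx] += t[:, None] * dirn[idx]


def transport_beam(
    phantom: PhantomModel | None,
    compensator: Compensator | None,
    beam: BeamSpec,
    n: int,
    rng: np.random.Generator,
    options: TransportOptions | None = None,
    z_source: float = -400.0,
    z_ref_in: float = -180.0,
    z_ref_out: float = 120.0,
    degrader_wet: float = 0.0,
) -> HistoryBatch:
    """Transport ``n`` protons from the source plane to the exit reference
    plane, through compensator (if any), an optional uniform degrader of
    water-equivalent thickness ``degrader_wet`` (used for calibration
    runs), and the phantom (if any).

    Returns a :class:`HistoryBatch`; protons that stop or undergo nuclear
    loss have NaN exit fields and the corresponding flag set.
    """
    if n < 1:
        raise ValueError("need at least one proton")
    opts = options or TransportOptions()

    # initial state: uniform disk, parallel beam
    r = beam.field_diameter / 2.0 * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.full(n, z_source)])
    d0 = np.asarray(beam.direction, float)
    dirn = np.tile(d0 / np.linalg.norm(d0), (n, 1))

    r0 = water_range(beam.energy) * np.ones(n)
    if opts.straggling:
        z_draw = rng.standard_normal(n)
        w_stop = np.clip(r0 * (1.0 + 0.011 * z_draw), 0.1, None)
    else:
        w_stop = r0.copy()
    wepl = np.zeros(n)
    stopped = np.zeros(n, dtype=bool)
    lost = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)

    # degrader: ideal uniform WET slab upstream of everything (calibration)
    if degrader_wet > 0:
        wepl += degrader_wet
        stopped |= wepl >= w_stop

    if compensator is not None:
        half = compensator.cube_side / 2.0
        z0, z1 = compensator.center_z - half, compensator.center_z + half
        _propagate_to_plane(pos, dirn, active & ~stopped & ~lost, z0)
        comp_rsp = compensator.material.rsp

        def comp_lookup(p):
            return comp_rsp * compensator_contains(p, compensator)

        _step_zone(pos, dirn, wepl, w_stop, active, stopped, lost,
                   z1, comp_lookup, compensator.material, r0, opts, rng)

    # entry reference plane (downstream of the compensator)
    ok = ~stopped & ~lost
    _propagate_to_plane(pos, dirn, ok, z_ref_in)
    entry_pos = pos.copy()
    entry_dir = dirn.copy()
    entry_pos[~ok] = np.nan
    entry_dir[~ok] = np.nan

    if phantom is not None:
        zc = float(np.asarray(phantom.body.center, float)[2])
        rad = phantom.body.radius
        _propagate_to_plane(pos, dirn, ok, zc - rad)

        def ph_lookup(p):
            return rsp_at(p, phantom)

        _step_zone(pos, dirn, wepl, w_stop, active, stopped, lost,
                   zc + rad, ph_lookup, phantom.body.material, r0, opts, rng)

    ok = ~stopped & ~lost
    _propagate_to_plane(pos, dirn, ok, z_ref_out)

    bad = ~ok
    exit_pos = pos.copy()
    exit_dir = dirn.copy()
    exit_pos[bad] = np.nan
    exit_dir[bad] = np.nan
    residual = np.where(ok, w_stop - wepl, 0.0)
    energy_out = np.where(ok, energy_from_range(np.clip(r0 - wepl, 0.0, None)), 0.0)

    return HistoryBatch(
        entry_pos=entry_pos,
        entry_dir=entry_dir,
        exit_pos=exit_pos,
        exit_dir=exit_dir,
        energy_in=np.full(n, beam.energy),
        energy_out=energy_out,
        true_wepl=wepl,
        residual_range=residual,
        stopped_in_phantom=stopped,
        nuclear_loss=lost,
        timestamp=np.arange(n, dtype=np.int64),
    )


def transport_history(
    phantom: PhantomModel | None,
    compensator: Compensator | None,
    beam: BeamSpec,
    rng: np.random.Generator,
    options: TransportOptions | None = None,
    **kwargs,
) -> ProtonHistory:
    """Transport a single proton (see :func:`transport_beam`)."""
    batch = transport_beam(phantom, compensator, beam, 1, rng, options, **kwargs)
    return batch.history(0)
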