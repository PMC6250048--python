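"""Analytic phantom and range-compensator geometry.

The imaged object is a sphere (PMMA by default) carrying cylindrical
tissue-substitute inserts with vertical axes, i.e. parallel to the
rotation axis of the scan, so every transverse slice through the insert
mid-section sees the same 2-D layout.  The compensator is a cube with a
spherical cavity of the same diameter as the phantom body: for rays
parallel to the beam axis inside the sphere silhouette, cavity chord plus
body chord is the constant cube side, which is what flattens the residual
range across the field.

All geometry here is exact (ray-sphere / ray-cylinder / ray-box
intersection intervals), making :func:`wepl_line_integral` the ground
truth oracle that detector-based WEPL estimates are judged against.
Coordinates are right-handed, lengths in mm, beam along +z, phantom
centre at the origin, rotation about +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .materials import MATERIALS, Material

__all__ = [
    "SphereBody",
    "CylinderInsert",
    "PhantomModel",
    "Compensator",
    "three_insert_phantom",
    "default_compensator",
    "rsp_at",
    "wepl_line_integral",
]


@dataclass(frozen=True)
class SphereBody:
    center: np.ndarray
    diameter: float
    material: Material

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class CylinderInsert:
    """Finite cylinder; ``axis`` is a unit vector (vertical by default)."""

    center: np.ndarray
    diameter: float
    length: float
    material: Material
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class PhantomModel:
    """Sphere body plus cylindrical inserts over a vacuum/air background.

    ``background=None`` means vacuum (rsp 0).  Inserts must lie inside the
    body; the innermost shape wins in RSP lookups.
    """

    body: SphereBody
    inserts: tuple[CylinderInsert, ...] = ()
    background: Material | None = None

    def __post_init__(self) -> None:
        if self.body.diameter <= 0:
            raise ValueError("body diameter must be positive")
        c0 = np.asarray(self.body.center, float)
        for ins in self.inserts:
            if ins.diameter <= 0 or ins.length <= 0:
                raise ValueError("insert dimensions must be positive")
            # farthest point of the cylinder from the body centre
            cc = np.asarray(ins.center, float) - c0
            axial = abs(float(cc @ ins.axis)) + ins.length / 2.0
            radial = np.linalg.norm(cc - (cc @ ins.axis) * ins.axis) + ins.radius
            if np.hypot(axial, radial) > self.body.radius + 1e-9:
                raise ValueError(f"insert {ins.material.name} not inside body")

    def rotated(self, angle_deg: float) -> "PhantomModel":
        """Phantom rotated by ``angle_deg`` about the +y axis through the
        body centre (the scanner's rotation stage)."""
        phi = np.deg2rad(angle_deg)
        c, s = np.cos(phi), np.sin(phi)
        rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        c0 = np.asarray(self.body.center, float)
        new_inserts = tuple(
            replace(
                ins,
                center=c0 + rot @ (np.asarray(ins.center, float) - c0),
                axis=rot @ np.asarray(ins.axis, float),
            )
            for ins in self.inserts
        )
        return replace(self, inserts=new_inserts)

    @property
    def background_rsp(self) -> float:
        return 0.0 if self.background is None else self.background.rsp


@dataclass(frozen=True)
class Compensator:
    """Cube-minus-sphere range compensator, fixed in the beam (it does not
    rotate with the phantom).  Centred on the beam axis at ``center_z``."""

    cube_side: float
    sphere_diameter: float
    material: Material
    center_z: float

    def __post_init__(self) -> None:
        if self.sphere_diameter > self.cube_side + 1e-9:
            raise ValueError("cavity sphere must fit inside the cube")

    @property
    def center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.center_z])


def three_insert_phantom(
    body_diameter: float = 75.0,
    insert_diameter: float = 15.0,
    insert_length: float = 50.0,
    insert_offset: float = 18.0,
    body_material: Material | None = None,
) -> PhantomModel:
    """The default imaging phantom: PMMA sphere with adipose-, bone- and
    water-equivalent cylinders 120 deg apart at ``insert_offset`` mm from
    the centre (water top-left, adipose top-right, bone at the bottom in
    the reconstructed slice)."""
    body_material = body_material or MATERIALS["pmma"]
    body = SphereBody(np.zeros(3), body_diameter, body_material)
    layout = {
        "water_equivalent": 150.0,
        "adipose": 30.0,
        "average_bone": 270.0,
    }
    inserts = []
    for name, alpha in layout.items():
        a = np.deg2rad(alpha)
        center = np.array([insert_offset * np.cos(a), 0.0, insert_offset * np.sin(a)])
        inserts.append(
            CylinderInsert(center, insert_diameter, insert_length, MATERIALS[name])
        )
    return PhantomModel(body, tuple(inserts))


def default_compensator(center_z: float = -232.5) -> Compensator:
    """75 mm PMMA cube with a 75 mm spherical cavity, upstream of the
    proximal tracker."""
    return Compensator(75.0, 75.0, MATERIALS["pmma"], center_z)


# ---------------------------------------------------------------------------
# point membership


def rsp_at(point, phantom: PhantomModel):
    """RSP at one or many points (mm).  Innermost shape wins: insert over
    body over background."""
    p = np.atleast_2d(np.asarray(point, float))
    out = np.full(p.shape[0], phantom.background_rsp)
    body_c = np.asarray(phantom.body.center, float)
    in_body = np.einsum("ij,ij->i", p - body_c, p - body_c) <= phantom.body.radius**2
    out[in_body] = phantom.body.material.rsp
    for ins in phantom.inserts:
        d = p - np.asarray(ins.center, float)
        ax = np.asarray(ins.axis, float)
        t = d @ ax
        radial2 = np.einsum("ij,ij->i", d, d) - t * t
        inside = (np.abs(t) <= ins.length / 2.0) & (radial2 <= ins.radius**2)
        out[inside] = ins.material.rsp
    if np.asarray(point).ndim == 1:
        return float(out[0])
    return out


def compensator_contains(point, comp: Compensator):
    """Boolean mask: inside the compensator material (cube minus cavity)."""
    p = np.atleast_2d(np.asarray(point, float))
    d = p - comp.center
    half = comp.cube_side / 2.0
    in_cube = np.all(np.abs(d) <= half, axis=1)
    in_cavity = np.einsum("ij,ij->i", d, d) <= (comp.sphere_diameter / 2.0) ** 2
    mask = in_cube & ~in_cavity
    if np.asarray(point).ndim == 1:
        return bool(mask[0])
    return mask


# ---------------------------------------------------------------------------
# exact segment intersections


def _interval_sphere(o, d, center, radius):
    """t-interval of the line o + t d (d unit) inside a sphere, or None."""
    oc = o - center
    b = oc @ d
    c = oc @ oc - radius * radius
    disc = b * b - c
    if disc <= 0:
        return None
    s = np.sqrt(disc)
    return (-b - s, -b + s)


def _interval_cylinder(o, d, ins: CylinderInsert):
    """t-interval inside a finite cylinder, or None."""
    ax = np.asarray(ins.axis, float)
    oc = o - np.asarray(ins.center, float)
    d_perp = d - (d @ ax) * ax
    o_perp = oc - (oc @ ax) * ax
    a = d_perp @ d_perp
    if a < 1e-16:
        # ray parallel to axis
        if o_perp @ o_perp > ins.radius**2:
            return None
        radial = (-np.inf, np.inf)
    else:
        b = o_perp @ d_perp
        c = o_perp @ o_perp - ins.radius**2
        disc = b * b - a * c
        if disc <= 0:
            return None
        s = np.sqrt(disc)
        radial = ((-b - s) / a, (-b + s) / a)
    da = d @ ax
    oa = oc @ ax
    h = ins.length / 2.0
    if abs(da) < 1e-16:
        if abs(oa) > h:
            return None
        axial = (-np.inf, np.inf)
    else:
        t1, t2 = (-h - oa) / da, (h - oa) / da
        axial = (min(t1, t2), max(t1, t2))
    lo, hi = max(radial[0], axial[0]), min(radial[1], axial[1])
    return (lo, hi) if hi > lo else None


def _interval_box(o, d, center, half):
    """Slab-method t-interval inside an axis-aligned cube, or None."""
    lo, hi = -np.inf, np.inf
    for k in range(3):
        if abs(d[k]) < 1e-16:
            if abs(o[k] - center[k]) > half:
                return None
            continue
        t1 = (center[k] - half - o[k]) / d[k]
        t2 = (center[k] + half - o[k]) / d[k]
        lo = max(lo, min(t1, t2))
        hi = min(hi, max(t1, t2))
    return (lo, hi) if hi > lo else None


def _clip(interval, lo, hi):
    if interval is None:
        return None
    a, b = max(interval[0], lo), min(interval[1], hi)
    return (a, b) if b > a else None


def _length(interval):
    return 0.0 if interval is None else interval[1] - interval[0]


def _overlap(i1, i2):
    if i1 is None or i2 is None:
        return None
    a, b = max(i1[0], i2[0]), min(i1[1], i2[1])
    return (a, b) if b > a else None


def compensator_wepl(entry, direction, comp: Compensator) -> float:
    """WEPL of the full line through the compensator along ``direction``
    from ``entry`` (both mm / unit vector)."""
    o = np.asarray(entry, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    cube = _interval_box(o, d, comp.center, comp.cube_side / 2.0)
    if cube is None:
        return 0.0
    cavity = _interval_sphere(o, d, comp.center, comp.sphere_diameter / 2.0)
    return comp.material.rsp * (_length(cube) - _length(_overlap(cube, cavity)))


def compensator_wepl_batch(points, dirs, comp: Compensator) -> np.ndarray:
    """Vectorised WEPL of full lines through the compensator.

    ``points`` (n,3) are points on the measured entry rays (anywhere on
    the line); ``dirs`` (n,3) the ray directions.  Used to subtract the
    beam-fixed compensator contribution from measured WEPLs.
    """
    p = np.atleast_2d(np.asarray(points, float))
    d = np.atleast_2d(np.asarray(dirs, float))
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    n = p.shape[0]
    half = comp.cube_side / 2.0
    center = comp.center
    lo = np.full(n, -np.inf)
    hi = np.full(n, np.inf)
    for k in range(3):
        dk = d[:, k]
        ok = np.abs(dk) > 1e-12
        t1 = np.where(ok, (center[k] - half - p[:, k]) / np.where(ok, dk, 1.0), -np.inf)
        t2 = np.where(ok, (center[k] + half - p[:, k]) / np.where(ok, dk, 1.0), np.inf)
        tlo, thi = np.minimum(t1, t2), np.maximum(t1, t2)
        miss_parallel = ~ok & (np.abs(p[:, k] - center[k]) > half)
        lo = np.maximum(lo, tlo)
        hi = np.minimum(hi, thi)
        hi = np.where(miss_parallel, lo, hi)
    cube_len = np.clip(hi - lo, 0.0, None)

    oc = p - center
    b = np.einsum("ij,ij->i", oc, d)
    c = np.einsum("ij,ij->i", oc, oc) - (comp.sphere_diameter / 2.0) ** 2
    disc = b * b - c
    s = np.sqrt(np.clip(disc, 0.0, None))
    s_lo, s_hi = -b - s, -b + s
    ov = np.clip(np.minimum(hi, s_hi) - np.maximum(lo, s_lo), 0.0, None)
    ov = np.where(disc > 0, ov, 0.0)
    return comp.material.rsp * (cube_len - ov)


def wepl_line_integral(
    entry,
    exit,
    phantom: PhantomModel | None = None,
    compensator: Compensator | None = None,
) -> float:
    """Exact straight-path WEPL (mm water-equivalent) between two points.

    Computes sum of rsp x segment length over every shape the segment
    crosses, with insert-over-body priority.  This is the line integral of
    RSP that a perfect proton-counting system would estimate.
    """
    o = np.asarray(entry, float)
    e = np.asarray(exit, float)
    seg = e - o
    length = np.linalg.norm(seg)
    if length == 0:
        raise ValueError("entry and exit must differ")
    d = seg / length
    wepl = 0.0
    if phantom is not None:
        body = _clip(
            _interval_sphere(o, d, np.asarray(phantom.body.center, float), phantom.body.radius),
            0.0,
            length,
        )
        body_rsp = phantom.body.material.rsp
        wepl += body_rsp * _length(body)
        if phantom.background is not None:
            wepl += phantom.background.rsp * (length - _length(body))
        for ins in phantom.inserts:
            seg_i = _clip(_overlap(_interval_cylinder(o, d, ins), body), 0.0, length)
            wepl += (ins.material.rsp - body_rsp) * _length(seg_i)
    if compensator is not None:
        cube = _clip(
            _interval_box(o, d, compensator.center, compensator.cube_side / 2.0),
            0.0,
            length,
        )
        cavity = _interval_sphere(
            o, d, compensator.center, compensator.sphere_diameter / 2.0
        )
        wepl += compensator.material.rsp * (
            _length(cube) - _length(_clip(_overlap(cube, cavity), 0.0, length))
        )
    return wepl
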