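import numpy as np
import pytest

from protonct.materials import MATERIALS
from protonct.phantom import PhantomModel, SphereBody
from protonct.recon import (
    Grid2D,
    SphereHull,
    backproject,
    bpf_filter,
    reconstruct,
    spline_path,
)
from protonct.tracker import EventArrays, TrackVector
from protonct.transport import BeamSpec, TransportOptions, transport_beam

HULL = SphereHull(np.zeros(3), 37.5)
GRID = Grid2D(128, 1.0)


def vec(point, direction, frame=0):
    d = np.asarray(direction, float)
    return TrackVector(np.asarray(point, float), d / np.linalg.norm(d), frame)


def straight_events(offsets, wepl=None, hull=HULL):
    """Parallel straight events along +z at the given x offsets."""
    n = len(offsets)
    entry = np.column_stack([offsets, np.zeros(n), np.full(n, -180.0)])
    exit = np.column_stack([offsets, np.zeros(n), np.full(n, 120.0)])
    d = np.tile([0.0, 0.0, 1.0], (n, 1))
    if wepl is None:
        wepl = 2.0 * np.sqrt(np.clip(hull.radius**2 - np.asarray(offsets) ** 2, 0, None))
    return EventArrays(np.arange(n), entry, d.copy(), exit, d.copy(),
                       np.zeros(n, np.int64), np.asarray(wepl, float), np.arange(n))


def truth_events(phantom, beam, n, rng, options=None, slab=10.0):
    batch = transport_beam(phantom, None, beam, n, rng, options)
    m = batch.alive
    t = (0.0 - batch.entry_pos[m][:, 2]) / batch.entry_dir[m][:, 2]
    y0 = batch.entry_pos[m][:, 1] + t * batch.entry_dir[m][:, 1]
    sel = np.abs(y0) < slab
    k = int(sel.sum())
    return EventArrays(np.arange(k),
                       batch.entry_pos[m][sel], batch.entry_dir[m][sel],
                       batch.exit_pos[m][sel], batch.exit_dir[m][sel],
                       np.zeros(k, np.int64), batch.true_wepl[m][sel],
                       np.arange(k))


class TestSplinePath:
    def test_collinear_is_straight(self):
        entry = vec([0.0, 0.0, -180.0], [0, 0, 1])
        exit = vec([0.0, 0.0, 120.0], [0, 0, 1])
        path = spline_path(entry, exit, HULL)
        assert not path.straight_fallback
        assert np.abs(path.points[:, 0]).max() < 1e-6
        assert np.abs(path.points[:, 1]).max() < 1e-6

    def test_path_length_at_least_chord(self):
        entry = vec([0.0, 0.0, -180.0], [0.05, 0, 1])
        exit = vec([5.0, 0.0, 120.0], [-0.05, 0, 1])
        path = spline_path(entry, exit, HULL)
        chord = np.linalg.norm(path.points[-1] - path.points[0])
        assert path.seg_lengths.sum() >= chord - 1e-9

    def test_antisymmetric_kink_peaks_at_mid_depth(self):
        """Mirror-symmetric entry/exit angles put the maximum lateral
        excursion at the middle of the path."""
        entry = vec([0.0, 0.0, -150.0], [0.08, 0, 1])
        exit = vec([0.0, 0.0, 150.0], [-0.08, 0, 1])
        path = spline_path(entry, exit, HULL, step=0.25)
        lateral = path.points[:, 0] - np.linspace(
            path.points[0, 0], path.points[-1, 0], len(path.points)
        )
        peak = np.argmax(np.abs(lateral))
        assert abs(peak / (len(path.points) - 1) - 0.5) < 0.1

    def test_missing_hull_falls_back_to_straight(self):
        entry = vec([60.0, 0.0, -180.0], [0, 0, 1])
        exit = vec([60.0, 0.0, 120.0], [0, 0, 1])
        assert spline_path(entry, exit, HULL).straight_fallback


class TestBackproject:
    def test_single_event_normalizes_to_rsp(self):
        """One straight diameter chord through uniform water: the
        per-unit-length normalized deposit equals RSP 1."""
        ev = straight_events([0.0])
        res = backproject(ev, GRID, HULL, spread="per-length")
        img = res.normalized()
        on_path = img[64, 30:98]
        np.testing.assert_allclose(on_path[on_path > 0], 1.0, rtol=1e-6)

    def test_crossing_events_accumulate_weight(self):
        n = 2
        entry = np.array([[0.0, 0.0, -180.0], [-180.0, 0.0, 0.0]])
        exit = np.array([[0.0, 0.0, 120.0], [120.0, 0.0, 0.0]])
        d = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        ev = EventArrays(np.arange(n), entry, d.copy(), exit, d.copy(),
                         np.zeros(n, np.int64), np.array([75.0, 75.0]),
                         np.arange(n))
        res = backproject(ev, GRID, HULL)
        solo = res.weights[64, 30]
        crossing = res.weights[64, 64]
        assert crossing > 1.5 * solo

    def test_uniform_slab_single_angle(self, rng):
        """Parallel coverage at one angle reconstructs RSP 1 inside with
        sd below 5% (per-unit-length mode)."""
        offsets = rng.uniform(-37.0, 37.0, size=10000)
        ev = straight_events(offsets)
        img = backproject(ev, GRID, HULL, spread="per-length").normalized()
        interior = img[40:88, 40:88]
        interior = interior[interior > 0]
        assert abs(interior.mean() - 1.0) < 0.01
        assert interior.std() < 0.05

    def test_nan_wepl_rejected(self):
        ev = straight_events([0.0], wepl=[np.nan])
        with pytest.raises(ValueError):
            backproject(ev, GRID, HULL)


class TestBpfFilter:
    @staticmethod
    def disk_backprojection(n, radius):
        c = (np.arange(n) - n / 2 + 0.5)
        X, Z = np.meshgrid(c, c, indexing="ij")
        nb = np.zeros((n, n))
        thetas = np.linspace(0, np.pi, 720, endpoint=False)
        for th in thetas:
            s = X * np.cos(th) + Z * np.sin(th)
            nb += 2 * np.sqrt(np.clip(radius**2 - s * s, 0, None))
        return nb / len(thetas), np.hypot(X, Z)

    def test_recovers_analytic_disk(self):
        """Deconvolving the analytically blurred unit disk returns the
        disk within 5% RMSE inside (2-voxel rim excluded)."""
        nb, r = self.disk_backprojection(128, 20.0)
        f = bpf_filter(nb, 1.0)
        inside = r < 18.0
        rmse = np.sqrt(np.mean((f[inside] - 1.0) ** 2))
        assert rmse < 0.05

    def test_zero_in_zero_out(self):
        out = bpf_filter(np.zeros((64, 64)), 1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linearity(self, rng):
        x = rng.normal(size=(64, 64))
        f1 = bpf_filter(3.5 * x, 1.0)
        f2 = 3.5 * bpf_filter(x, 1.0)
        np.testing.assert_allclose(f1, f2, rtol=1e-10, atol=1e-10)

    def test_invalid_voxel_rejected(self):
        with pytest.raises(ValueError):
            bpf_filter(np.zeros((8, 8)), 0.0)
        with pytest.raises(ValueError):
            bpf_filter(np.zeros(8), 1.0)


class TestReconstruct:
    def test_requires_two_angles(self):
        with pytest.raises(ValueError):
            reconstruct([(0.0, straight_events([0.0]))], GRID, HULL)

    def test_uniform_water_sphere(self, water_sphere, rng):
        """36 x 1e4 truth events: interior RSP 1.00 +- 0.05 and hull
        exterior near zero."""
        beam = BeamSpec(125.0, 85.0)
        opts = TransportOptions(nuclear=False)
        projs = [
            (ang, truth_events(water_sphere.rotated(ang), beam, 10000, rng, opts))
            for ang in np.arange(36) * 10.0
        ]
        img = reconstruct(projs, GRID, HULL)
        c = (np.arange(128) - 63.5)
        X, Z = np.meshgrid(c, c, indexing="ij")
        r = np.hypot(X, Z)
        interior = img.data[r < 30]
        assert abs(interior.mean() - 1.0) < 0.05
        assert interior.std() < 0.06
        exterior = img.data[(r > 45) & (r < 60)]
        assert abs(exterior.mean()) < 0.02

    def test_noise_scales_with_events(self, water_sphere, rng):
        """Doubling the event count cuts interior noise by ~1/sqrt(2).
        Noise is isolated as the difference of two independent scans."""
        beam = BeamSpec(125.0, 85.0)
        opts = TransportOptions(nuclear=False)
        angles = np.arange(18) * 20.0

        def scan(n):
            projs = [
                (a, truth_events(water_sphere.rotated(a), beam, n, rng, opts))
                for a in angles
            ]
            return reconstruct(projs, GRID, HULL).data

        c = (np.arange(128) - 63.5)
        X, Z = np.meshgrid(c, c, indexing="ij")
        mask = np.hypot(X, Z) < 25
        noise_small = (scan(4000) - scan(4000))[mask].std() / np.sqrt(2)
        noise_big = (scan(8000) - scan(8000))[mask].std() / np.sqrt(2)
        ratio = noise_small / noise_big
        assert np.sqrt(2) * 0.8 < ratio < np.sqrt(2) * 1.2

    def test_straight_and_spline_agree_without_scattering(self, water_sphere, rng):
        """With scattering off, entry/exit rays are collinear and the
        Hermite path degenerates to the chord: reconstructions agree."""
        beam = BeamSpec(125.0, 85.0)
        opts = TransportOptions(scattering=False, straggling=False, nuclear=False)
        angles = np.arange(12) * 30.0
        projs = [
            (a, truth_events(water_sphere.rotated(a), beam, 4000, rng, opts))
            for a in angles
        ]
        img_spline = reconstruct(projs, GRID, HULL).data
        straight = []
        for a, ev in projs:
            chord_d = ev.exit_point - ev.entry_point
            chord_d /= np.linalg.norm(chord_d, axis=1, keepdims=True)
            straight.append((a, EventArrays(
                ev.frame_index, ev.entry_point, chord_d,
                ev.exit_point, chord_d.copy(), ev.rt_last_layer,
                ev.wepl, ev.proton)))
        img_straight = reconstruct(straight, GRID, HULL).data
        c = (np.arange(128) - 63.5)
        X, Z = np.meshgrid(c, c, indexing="ij")
        mask = np.hypot(X, Z) < 30
        assert np.abs(img_spline - img_straight)[mask].mean() < 0.01
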