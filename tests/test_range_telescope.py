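import numpy as np
import pytest

from protonct.detector import RTGeometry, StripFrame, rt_crossings
from protonct.materials import water_range
from protonct.range_telescope import (
    CalibrationError,
    CalibrationTable,
    PunchThroughError,
    RTTrack,
    assign_wepl,
    assign_wepl_array,
    build_calibration,
    extract_range,
    fluence_depth_curve,
    follow_rt_tracks,
    range_uncertainty,
)
from protonct.transport import BeamSpec, TransportOptions, transport_beam

RT = RTGeometry()


def layer_frames(hits_by_layer):
    """StripFrames (frame 0) for {layer: [x positions]}."""
    plane0 = RT.plane(0)
    frames = []
    for layer in range(RT.n_layers):
        xs = hits_by_layer.get(layer, [])
        strips = [int(np.floor((x - plane0.m_min) / plane0.pitch)) for x in xs]
        frames.append(StripFrame(100 + layer, 0, np.array(strips, dtype=int),
                                 np.zeros(len(strips), bool)))
    return frames


def stopping_layers(energy, n, rng, degrader=0.0, nuclear=True):
    beam = BeamSpec(energy=energy, field_diameter=60.0)
    opts = TransportOptions(nuclear=nuclear)
    batch = transport_beam(None, None, beam, n, rng, options=opts,
                           degrader_wet=degrader)
    cross = rt_crossings(batch, RT, rng, nuclear=nuclear)
    return cross["true_last"]


class TestTrackFollowing:
    def test_single_track_stopping_layer(self):
        tracks = follow_rt_tracks(layer_frames({l: [5.0] for l in range(13)}), RT)
        assert len(tracks) == 1
        assert tracks[0].last_layer == 12
        assert not tracks[0].punch_through

    def test_reaching_last_layer_sets_veto(self):
        tracks = follow_rt_tracks(layer_frames({l: [0.0] for l in range(21)}), RT)
        assert tracks[0].punch_through

    def test_single_gap_bridged_two_gaps_terminate(self):
        hits = {l: [1.0] for l in range(13) if l != 7}
        tracks = follow_rt_tracks(layer_frames(hits), RT)
        assert tracks[0].last_layer == 12
        hits2 = {l: [1.0] for l in range(13) if l not in (7, 8)}
        tracks2 = follow_rt_tracks(layer_frames(hits2), RT)
        assert tracks2[0].last_layer == 6

    def test_two_separated_tracks(self):
        hits = {}
        for l in range(9):
            hits.setdefault(l, []).append(-20.0)
        for l in range(15):
            hits.setdefault(l, []).append(20.0)
        tracks = follow_rt_tracks(layer_frames(hits), RT)
        got = sorted((round(t.layer_hits[0][1]), t.last_layer) for t in tracks)
        assert got == [(-20, 8), (20, 14)]

    def test_displacement_window_rejects_far_hit(self):
        hits = {0: [0.0], 1: [10.0]}
        tracks = follow_rt_tracks(layer_frames(hits), RT)
        assert tracks[0].last_layer == 0


class TestRangeBudget:
    def test_quoted_budget_for_125_mev(self):
        """sigma_r = 1.5 mm, 1.3% of the beam range, for 2.6 mm layers."""
        b = range_uncertainty(water_range(125.0), 2.6)
        assert round(b.sigma_total, 1) == 1.5
        assert round(b.fraction_of_range, 1) == 1.3

    def test_hand_arithmetic_100mm(self):
        b = range_uncertainty(100.0, 2.6)
        assert b.sigma_total == pytest.approx(1.332, abs=2e-3)

    def test_zero_layer_thickness(self):
        b = range_uncertainty(100.0, 0.0)
        assert b.sigma_total == pytest.approx(1.1)

    def test_quadrature_identity(self):
        b = range_uncertainty(80.0, 2.6)
        assert b.sigma_total**2 == pytest.approx(
            b.sigma_straggle**2 + b.sigma_layer**2
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            range_uncertainty(0.0, 2.6)
        with pytest.raises(ValueError):
            range_uncertainty(100.0, -1.0)

    def test_stopping_layer_spread_matches_budget(self, rng):
        """Measured stopping-layer sd (in mm) agrees with the analytic
        quadrature budget within 15%."""
        beam_range = water_range(125.0)
        last = stopping_layers(125.0, 10000, rng, degrader=87.0, nuclear=False)
        last = last[last >= 0]
        measured_mm = last.std() * RT.wet_per_layer
        budget = range_uncertainty(beam_range, RT.wet_per_layer).sigma_total
        assert abs(measured_mm - budget) / budget < 0.15


class TestFluenceDepth:
    def test_step_function_when_all_stop_together(self):
        curve = fluence_depth_curve(np.full(500, 7))
        assert curve[7] == 1.0
        assert len(curve) == 8

    def test_non_increasing(self, rng):
        curve = fluence_depth_curve(stopping_layers(70.0, 4000, rng))
        assert np.all(np.diff(curve) <= 1e-12)

    def test_gradual_decline_before_falloff(self, rng):
        """Nuclear losses produce a negative pre-falloff slope."""
        curve = fluence_depth_curve(stopping_layers(81.0, 20000, rng))
        plateau = curve[1:12]  # well before the ~layer-20 falloff
        slope = np.polyfit(np.arange(plateau.size), plateau, 1)[0]
        assert slope < 0

    def test_range_ordering_with_energy(self, rng):
        """Extracted 50%-falloff range grows monotonically with beam
        energy across the 32-81 MeV window."""
        ranges = []
        for e in [32.0, 45.0, 58.0, 70.0, 81.0]:
            curve = fluence_depth_curve(stopping_layers(e, 3000, rng))
            ranges.append(extract_range(curve))
        assert all(b > a for a, b in zip(ranges, ranges[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fluence_depth_curve(np.array([], dtype=int))


class TestCalibration:
    def build(self, rng, wets=None, n=1500):
        settings = []
        for w in (wets if wets is not None else np.arange(59.0, 111.0, 1.0)):
            layers = stopping_layers(125.0, n, rng, degrader=float(w))
            settings.append((float(w), layers[layers >= 0]))
        return build_calibration(settings, 125.0, RT)

    def test_two_settings_interpolate_monotonically(self, rng):
        calib = self.build(rng, wets=[70.0, 95.0])
        assert np.all(np.diff(calib.residual_wet) > 0)

    def test_layer_increment_near_layer_wet(self, rng):
        calib = self.build(rng)
        incr = np.diff(calib.residual_wet[3:18])
        assert np.all(np.abs(incr - RT.wet_per_layer) < 1.0)

    def test_non_monotone_data_rejected(self):
        settings = [(60.0, np.full(100, 5)), (80.0, np.full(100, 9))]
        with pytest.raises(CalibrationError):
            build_calibration(settings, 125.0, RT)

    def test_too_few_settings_rejected(self):
        with pytest.raises(CalibrationError):
            build_calibration([(60.0, np.full(10, 5))], 125.0, RT)

    def test_closed_loop_degrader_recovery(self, rng):
        """Calibrate, then measure known degraders: bias < 0.5 mm across
        the 65-105 mm range (an 81-32 MeV residual sweep).  Nuclear-
        truncated tracks are excluded from the measurement here -- in the
        scan pipeline the WEPL quality gate removes that tail."""
        calib = self.build(rng)
        for w in [65.0, 75.0, 85.0, 95.0, 105.0]:
            layers = stopping_layers(125.0, 3000, rng, degrader=w, nuclear=False)
            layers = layers[(layers > 0) & (layers < RT.veto_layers[1])]
            wepl = assign_wepl_array(layers, calib)
            assert abs(wepl.mean() - w) < 0.5

    def test_assign_wepl_layer_increment(self, rng):
        calib = self.build(rng)
        w_lo = assign_wepl(RTTrack(0, [(0, 0.0)], 10), calib)
        w_hi = assign_wepl(RTTrack(0, [(0, 0.0)], 11), calib)
        assert w_lo - w_hi == pytest.approx(
            calib.residual_wet[11] - calib.residual_wet[10]
        )
        assert abs((w_lo - w_hi) - RT.wet_per_layer) < 1.0

    def test_punch_through_rejected(self, rng):
        calib = self.build(rng, wets=[70.0, 95.0])
        with pytest.raises(PunchThroughError):
            assign_wepl(RTTrack(0, [(0, 0.0)], 20, punch_through=True), calib)

    def test_calibration_table_invariant(self):
        with pytest.raises(CalibrationError):
            CalibrationTable(np.array([3.0, 2.0, 5.0]), 125.0)
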