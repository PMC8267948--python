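"""Generator contracts: velocity fields, lattice wave propagation, electrogram
synthesis with capture logic, and action-potential waveforms."""

import math

import numpy as np
import pytest

import atriamap as am
from atriamap.synthetic_tissue import TISSUE_MARGIN_MM, biphasic_wavelet


class TestVelocityField:
    def test_zero_heterogeneity_gives_constant_field_at_commanded_mean(self, grid):
        f = am.build_velocity_field(grid, 0.341, 0.0, seed=3)
        assert np.all(f.speeds == 0.341)

    def test_zero_heterogeneity_consumes_no_randomness(self, grid):
        f1 = am.build_velocity_field(grid, 0.3, 0.0, seed=1)
        f2 = am.build_velocity_field(grid, 0.3, 0.0, seed=2)
        np.testing.assert_array_equal(f1.speeds, f2.speeds)

    def test_sample_mean_exact_after_renormalization(self, grid):
        f = am.build_velocity_field(grid, 0.3, 0.4, seed=7)
        assert f.speeds.mean() == pytest.approx(0.3, rel=1e-12)
        assert np.all(f.speeds > 0)

    def test_empirical_cv_matches_commanded_on_fine_lattice(self, grid):
        # >= 2500 nodes via a finer lattice
        f = am.build_velocity_field(grid, 0.3, 0.4, seed=7, fine_spacing_mm=0.04)
        assert f.speeds.size >= 2500
        emp_cv = f.speeds.std() / f.speeds.mean()
        assert emp_cv == pytest.approx(0.4, rel=0.25)

    def test_seed_determinism(self, grid):
        f1 = am.build_velocity_field(grid, 0.3, 0.3, seed=11)
        f2 = am.build_velocity_field(grid, 0.3, 0.3, seed=11)
        np.testing.assert_array_equal(f1.speeds, f2.speeds)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mean_speed_mps": -0.1, "cv_frac": 0.1},
            {"mean_speed_mps": 0.0, "cv_frac": 0.1},
            {"mean_speed_mps": 0.3, "cv_frac": -0.2},
            {"mean_speed_mps": 0.3, "cv_frac": 0.1, "correlation_length_mm": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, grid, kwargs):
        with pytest.raises(am.InvalidParameterError):
            am.build_velocity_field(grid, **kwargs)


class TestSimulateActivation:
    def test_axis_aligned_travel_time_closed_form(self, grid):
        # constant 0.25 mm/ms field, stimulus at an electrode: 2 mm along a row -> 8 ms
        f = am.build_velocity_field(grid, 0.25, 0.0)
        act = am.simulate_activation(f, (0.0, 0.0))
        lats = act.sample_at(grid.positions_mm())
        assert lats[0] == pytest.approx(0.0, abs=1e-12)
        assert lats[4] == pytest.approx(8.0, rel=1e-12)  # (2.0 mm, 0.0) electrode

    def test_diagonal_travel_time_closed_form(self, grid):
        f = am.build_velocity_field(grid, 0.25, 0.0)
        act = am.simulate_activation(f, (0.0, 0.0))
        lats = act.sample_at(grid.positions_mm())
        assert lats[-1] == pytest.approx(2.0 * math.sqrt(2) / 0.25, rel=1e-12)

    def test_stimulus_outside_bounds_rejected(self, grid):
        f = am.build_velocity_field(grid, 0.3, 0.0)
        with pytest.raises(am.OutOfDomainError):
            am.simulate_activation(f, (50.0, 0.0))

    def test_heterogeneous_times_match_exhaustive_dijkstra_oracle(self, grid):
        """Independent shortest-path oracle (networkx) on a small lattice."""
        networkx = pytest.importorskip("networkx")
        f = am.build_velocity_field(grid, 0.3, 0.4, seed=5, fine_spacing_mm=0.1)
        sub = am.VelocityField(origin_mm=f.origin_mm, spacing_mm=0.1, speeds=f.speeds[:9, :9])
        act = am.simulate_activation(sub, sub.origin_mm)
        g = networkx.Graph()
        ny, nx = sub.shape
        for iy in range(ny):
            for ix in range(nx):
                for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
                    jy, jx = iy + dy, ix + dx
                    if 0 <= jy < ny and 0 <= jx < nx:
                        length = 0.1 * math.hypot(dy, dx)
                        w = length * 0.5 * (1 / sub.speeds[iy, ix] + 1 / sub.speeds[jy, jx])
                        g.add_edge((iy, ix), (jy, jx), weight=w)
        ref = networkx.single_source_dijkstra_path_length(g, (0, 0))
        for (iy, ix), t_ref in ref.items():
            assert act.times_ms[iy, ix] == pytest.approx(t_ref, rel=1e-9)

    def test_adjacent_node_gradient_bound(self, grid):
        f = am.build_velocity_field(grid, 0.3, 0.4, seed=5)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        t = act.times_ms
        vmin_x = np.minimum(f.speeds[:, 1:], f.speeds[:, :-1])
        assert np.all(np.abs(np.diff(t, axis=1)) <= 0.1 / vmin_x + 1e-9)

    def test_octile_error_bound_on_constant_field(self, grid):
        bound = 1 / math.cos(math.radians(22.5)) - 1  # ~8.24%
        f = am.build_velocity_field(grid, 0.3, 0.0)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        xs, ys = f.node_coords_mm()
        xx, yy = np.meshgrid(xs, ys)
        x0, y0 = am.corner_position(f, "LAA")
        euclid = np.hypot(xx - x0, yy - y0) / 0.3
        rel = (act.times_ms[euclid > 0] - euclid[euclid > 0]) / euclid[euclid > 0]
        assert rel.min() >= -1e-9  # lattice paths never beat the straight line
        assert rel.max() <= bound + 1e-9

    def test_lattice_refinement_converges_on_heterogeneous_field(self, grid):
        """Coarser subsamplings of one fixed speed field deviate more from the
        fine-lattice solution than intermediate ones (monotone refinement)."""
        fine = am.build_velocity_field(grid, 0.3, 0.3, seed=9, fine_spacing_mm=0.025)
        act_ref = am.simulate_activation(fine, am.corner_position(fine, "LAA"))
        ref = act_ref.sample_at(grid.positions_mm())
        errs = []
        for step in (2, 4):  # 0.05 mm and 0.1 mm lattices of the same field
            coarse = am.VelocityField(
                origin_mm=fine.origin_mm,
                spacing_mm=fine.spacing_mm * step,
                speeds=fine.speeds[::step, ::step],
            )
            act = am.simulate_activation(coarse, am.corner_position(coarse, "LAA"))
            errs.append(np.max(np.abs(act.sample_at(grid.positions_mm()) - ref)))
        assert errs[0] <= errs[1]


class TestSynthesizeRecording:
    def test_s1_train_deflections_periodic_at_cycle_length(self, grid):
        f = am.build_velocity_field(grid, 0.3, 0.0)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        rec = am.synthesize_s1_train(act, grid, 200.0, n_beats=4)
        dt = rec.dt_ms
        for ch in range(grid.n_channels):
            v = np.abs(rec.traces[ch])
            centers = []
            for ev in rec.stimulus_log:
                i0 = int(ev.t_ms / dt)
                i1 = int((ev.t_ms + 40.0) / dt)
                centers.append(np.argmax(v[i0:i1]) + i0)
            assert np.all(np.diff(centers) * dt == 200.0)

    def test_s2_capture_threshold_at_true_erp(self, grid):
        # ERP_true(400 ms) = 84 ms: S2 at CI 90 captures, CI 80 leaves no deflections
        tissue = am.TissueModel(erp_min_ms=84.0, erp_gain_ms=0.0)
        f = am.build_velocity_field(grid, 0.3, 0.0)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        rec = am.synthesize_erp_sweep(act, grid, tissue, 400.0)
        s2 = [ev for ev in rec.stimulus_log if ev.kind == "S2"]
        assert [ev.ci_ms for ev in s2] == [100.0, 90.0, 80.0]
        assert rec.truth["s2_captured"] == [True, True, False]
        dt = rec.dt_ms
        last = s2[-1]
        window = rec.traces[:, int((last.t_ms + 2) / dt) : int((last.t_ms + 40) / dt)]
        assert np.max(np.abs(window)) == 0.0  # no propagated response

    def test_noise_free_lat_round_trip_within_one_sample(self, grid):
        f = am.build_velocity_field(grid, 0.3, 0.3, seed=21)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        rec = am.synthesize_s1_train(act, grid, 200.0)
        amap = am.build_activation_map(rec, len(rec.stimulus_log) - 1)
        truth = np.array([rec.truth["lat_ms"][n] for n in grid.channel_names()])
        assert amap.n_annotated == grid.n_channels
        assert np.max(np.abs(amap.lat_ms.ravel() - truth)) < 0.5

    def test_seeded_noise_is_reproducible(self, grid):
        f = am.build_velocity_field(grid, 0.3, 0.0)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        r1 = am.synthesize_s1_train(act, grid, 200.0, noise_sd_mv=0.05, seed=42)
        r2 = am.synthesize_s1_train(act, grid, 200.0, noise_sd_mv=0.05, seed=42)
        np.testing.assert_array_equal(r1.traces, r2.traces)

    def test_too_coarse_sampling_rejected(self, grid):
        f = am.build_velocity_field(grid, 0.3, 0.0)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        with pytest.raises(am.ResolutionError):
            am.synthesize_s1_train(act, grid, 200.0, sampling_rate_hz=500.0)

    def test_wavelet_peak_at_center_and_biphasic(self):
        t = np.linspace(-6.0, 6.0, 1201)
        w = biphasic_wavelet(t)
        assert np.argmax(np.abs(w)) == np.argmin(np.abs(t))
        assert w.min() < 0 < w.max()  # biphasic
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)  # symmetric

    def test_margin_keeps_corner_channel_clear_of_blanking(self, grid):
        assert TISSUE_MARGIN_MM * math.sqrt(2) / 0.353 > 2.0


class TestSynthesizeActionPotential:
    @pytest.mark.parametrize("targets", [(4.74, 12.19, 33.09), (8.93, 19.94, 49.31)])
    def test_measured_apd_matches_commanded_targets(self, targets):
        trace = am.synthesize_action_potential(targets)
        res = am.measure_apd(trace)
        assert res.apd20_ms == pytest.approx(targets[0], abs=0.5)
        assert res.apd50_ms == pytest.approx(targets[1], abs=0.5)
        assert res.apd90_ms == pytest.approx(targets[2], abs=0.5)

    def test_repolarization_is_monotone_after_plateau(self):
        trace = am.synthesize_action_potential((10.0, 25.0, 45.0))
        v = trace.voltage_mv
        i_peak = int(np.argmax(v))
        assert np.all(np.diff(v[i_peak:]) <= 1e-12)

    def test_non_increasing_targets_rejected(self):
        with pytest.raises(am.InvalidParameterError):
            am.synthesize_action_potential((10.0, 9.0, 45.0))
        with pytest.raises(am.InvalidParameterError):
            am.synthesize_action_potential((10.0, 25.0, 45.0), rest_mv=30.0, peak_mv=20.0)

    def test_seeded_noise_reproducible(self):
        t1 = am.synthesize_action_potential((10, 25, 45), noise_sd_mv=1.0, seed=5)
        t2 = am.synthesize_action_potential((10, 25, 45), noise_sd_mv=1.0, seed=5)
        np.testing.assert_array_equal(t1.voltage_mv, t2.voltage_mv)


class TestTissueModel:
    def test_restitution_strictly_increasing_with_positive_gain(self):
        t = am.TissueModel(erp_min_ms=50, erp_gain_ms=30, erp_tau_ms=200)
        cls = [100, 200, 300, 400]
        erps = [t.erp_true_ms(c) for c in cls]
        assert np.all(np.diff(erps) > 0)

    def test_invalid_model_rejected(self):
        with pytest.raises(am.InvalidParameterError):
            am.TissueModel(velocity_mean_mps=0.0)
        with pytest.raises(am.InvalidParameterError):
            am.TissueModel(apd_targets_ms=(10.0, 9.0, 45.0))
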