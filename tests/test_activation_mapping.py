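"""LAT detection, activation-map assembly and total activation time."""

import math

import numpy as np
import pytest

import atriamap as am
from atriamap.activation_mapping import MappingConfig
from atriamap.synthetic_tissue import biphasic_wavelet


def _trace_with_deflection(center_ms, fs=2000.0, dur_ms=100.0, amp=1.0, noise=0.0, seed=0):
    t = np.arange(0, dur_ms, 1000.0 / fs)
    v = biphasic_wavelet(t - center_ms, amp)
    if noise > 0:
        v = v + np.random.default_rng(seed).normal(0, noise, v.shape)
    return v


class TestDetectLat:
    def test_noise_free_deflection_detected_at_center(self):
        v = _trace_with_deflection(50.0)
        lat = am.detect_lat(v, 2000.0, (40.0, 70.0), (10.0, 35.0))
        assert lat == pytest.approx(50.0, abs=0.05)

    def test_off_sample_center_recovered_with_subsample_precision(self):
        v = _trace_with_deflection(50.21)
        lat = am.detect_lat(v, 2000.0, (40.0, 70.0), (10.0, 35.0))
        assert lat == pytest.approx(50.21, abs=0.05)

    def test_pure_noise_window_returns_absent(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 0.05, 200)
        assert am.detect_lat(v, 2000.0, (40.0, 70.0), (10.0, 35.0)) is None

    def test_noisy_detection_monte_carlo_within_one_ms(self):
        hits = 0
        for seed in range(200):
            v = _trace_with_deflection(50.0, noise=0.05, seed=seed)  # 5% of amplitude
            lat = am.detect_lat(v, 2000.0, (40.0, 70.0), (10.0, 35.0))
            hits += lat is not None and abs(lat - 50.0) <= 1.0
        assert hits >= 190  # >= 95%

    def test_empty_or_misordered_windows_rejected(self):
        v = _trace_with_deflection(50.0)
        with pytest.raises(am.InvalidParameterError):
            am.detect_lat(v, 2000.0, (70.0, 40.0), (10.0, 35.0))
        with pytest.raises(am.InvalidParameterError):
            am.detect_lat(v, 2000.0, (40.0, 70.0), (45.0, 60.0))

    def test_amplitude_invariance_of_detection(self):
        v = _trace_with_deflection(50.0, noise=0.05, seed=3)
        lat1 = am.detect_lat(v, 2000.0, (40.0, 70.0), (10.0, 35.0))
        lat2 = am.detect_lat(100.0 * v, 2000.0, (40.0, 70.0), (10.0, 35.0))
        assert lat1 == pytest.approx(lat2, abs=1e-9)


@pytest.fixture(scope="module")
def mapped_recording():
    grid = am.ElectrodeGrid()
    field = am.build_velocity_field(grid, 0.3, 0.25, seed=13)
    act = am.simulate_activation(field, am.corner_position(field, "LAA"))
    rec = am.synthesize_s1_train(act, grid, 200.0, n_beats=6)
    return rec


class TestBuildActivationMap:
    def test_round_trip_against_generator_sidecar(self, mapped_recording):
        rec = mapped_recording
        amap = am.build_activation_map(rec, 3)
        truth = np.array([rec.truth["lat_ms"][n] for n in rec.grid.channel_names()])
        assert amap.n_annotated == 25
        np.testing.assert_allclose(amap.lat_ms.ravel(), truth, atol=0.5)

    def test_stimulus_corner_channel_has_smallest_lat(self, mapped_recording):
        amap = am.build_activation_map(mapped_recording, 3)
        assert np.nanargmin(amap.lat_ms.ravel()) == 0  # LAA corner = (row 0, col 0)

    def test_out_of_range_beat_index_rejected(self, mapped_recording):
        with pytest.raises(am.InvalidParameterError):
            am.build_activation_map(mapped_recording, 99)

    def test_non_captured_s2_yields_empty_map(self):
        grid = am.ElectrodeGrid()
        tissue = am.TissueModel(erp_min_ms=84.0, erp_gain_ms=0.0)
        f = am.build_velocity_field(grid, 0.3, 0.0)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        rec = am.synthesize_erp_sweep(act, grid, tissue, 400.0)
        failed_s2 = max(
            i for i, ev in enumerate(rec.stimulus_log) if ev.kind == "S2"
        )
        amap = am.build_activation_map(rec, failed_s2)
        assert amap.n_annotated == 0

    def test_translation_invariance_of_relative_lats(self, mapped_recording):
        rec = mapped_recording
        shift = 100  # samples
        shifted = am.Recording(
            grid=rec.grid,
            sampling_rate_hz=rec.sampling_rate_hz,
            traces=np.pad(rec.traces, ((0, 0), (shift, 0))),
            stimulus_log=am.StimulusLog(
                [
                    am.StimulusEvent(
                        t_ms=ev.t_ms + shift * rec.dt_ms,
                        kind=ev.kind,
                        corner=ev.corner,
                        ci_ms=ev.ci_ms,
                        cl_ms=ev.cl_ms,
                    )
                    for ev in rec.stimulus_log
                ]
            ),
        )
        m1 = am.build_activation_map(rec, 3)
        m2 = am.build_activation_map(shifted, 3)
        np.testing.assert_allclose(m1.lat_ms, m2.lat_ms, atol=1e-9)

    def test_amplitude_invariance_of_map(self, mapped_recording):
        rec = mapped_recording
        scaled = am.Recording(
            grid=rec.grid,
            sampling_rate_hz=rec.sampling_rate_hz,
            traces=rec.traces * 37.0,
            stimulus_log=rec.stimulus_log,
        )
        m1 = am.build_activation_map(rec, 3)
        m2 = am.build_activation_map(scaled, 3)
        np.testing.assert_allclose(m1.lat_ms, m2.lat_ms, atol=1e-9)


class TestTotalActivationTime:
    def test_max_minus_min(self, grid):
        lat = np.full((5, 5), np.nan)
        lat[0, :3] = [0.0, 1.5, 4.2]
        amap = am.ActivationMap(grid=grid, lat_ms=lat)
        assert am.total_activation_time(amap) == pytest.approx(4.2)

    def test_uniform_map_has_zero_tat(self, grid):
        amap = am.ActivationMap(grid=grid, lat_ms=np.full((5, 5), 3.3))
        assert am.total_activation_time(amap) == 0.0

    def test_offset_invariance(self, grid):
        rng = np.random.default_rng(2)
        lat = rng.uniform(0, 10, (5, 5))
        t1 = am.total_activation_time(am.ActivationMap(grid=grid, lat_ms=lat))
        t2 = am.total_activation_time(am.ActivationMap(grid=grid, lat_ms=lat + 7.7))
        assert t1 == pytest.approx(t2)
        assert t1 >= 0

    def test_single_annotation_rejected(self, grid):
        lat = np.full((5, 5), np.nan)
        lat[0, 0] = 1.0
        with pytest.raises(am.InsufficientDataError):
            am.total_activation_time(am.ActivationMap(grid=grid, lat_ms=lat))

    def test_corner_paced_tat_matches_lattice_metric(self, grid):
        """Wave at 0.25 mm/ms from the tissue corner: TAT equals the octile-path
        travel-time difference between the farthest and nearest electrodes."""
        f = am.build_velocity_field(grid, 0.25, 0.0)
        act = am.simulate_activation(f, am.corner_position(f, "LAA"))
        rec = am.synthesize_s1_train(act, grid, 200.0, n_beats=6)
        amap = am.build_activation_map(rec, 5)
        expected = 2.0 * math.sqrt(2) / 0.25  # both extreme electrodes lie on the diagonal
        assert am.total_activation_time(amap) == pytest.approx(expected, abs=0.05)


def test_configurable_threshold_changes_sensitivity():
    v = _trace_with_deflection(50.0, amp=0.45, noise=0.05, seed=11)
    strict = MappingConfig(threshold_k=12.0)
    assert am.detect_lat(v, 2000.0, (40.0, 70.0), (10.0, 35.0), config=strict) is None
    assert am.detect_lat(v, 2000.0, (40.0, 70.0), (10.0, 35.0)) is not None
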