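"""PRF thermometry: scaling, inversion, drift, unwrapping, probe comparison."""

import numpy as np
import pytest

import mrgfus as m
from conftest import make_meta


def _cfg(**kw):
    defaults = dict(f0_MHz=300.0, TE_ms=10.0, alpha_ppm_per_C=-0.01)
    defaults.update(kw)
    return m.ThermometryConfig(**defaults)


class TestDeltaTMap:
    def test_frame_equals_baseline_gives_zero(self):
        z = np.exp(1j * np.linspace(-2, 2, 64)).reshape(1, 8, 8)
        dT = m.delta_T_map(z, z, _cfg())
        np.testing.assert_allclose(dT, 0.0, atol=1e-12)

    def test_hand_scaled_phase_shift(self):
        """-0.1885 rad at alpha=-0.01 ppm/°C, f0=300 MHz, TE=10 ms -> +1 °C.

        2*pi * (-0.01e-6 * 300e6) Hz/°C * 0.010 s = -0.18850 rad/°C.
        """
        base = np.ones((1, 4, 4), complex)
        frame = np.exp(1j * -0.18849555921538757) * base
        dT = m.delta_T_map(frame, base, _cfg())
        np.testing.assert_allclose(dT, 1.0, atol=1e-9)

    def test_heating_is_positive_with_negative_alpha(self):
        base = np.ones((1, 4, 4), complex)
        frame = np.exp(-0.1j) * base  # phase decrease at the later frame
        assert np.all(m.delta_T_map(frame, base, _cfg()) > 0)
        cfg_flipped = _cfg(flip_sign=True)
        assert np.all(m.delta_T_map(frame, base, cfg_flipped) < 0)

    def test_zero_magnitude_flagged(self):
        base = np.ones((1, 4, 4), complex)
        frame = base.copy()
        frame[0, 1, 1] = 0.0
        dT = m.delta_T_map(frame, base, _cfg())
        assert np.isnan(dT[0, 1, 1])
        assert np.isfinite(np.delete(dT.ravel(), 5)).all()

    def test_alpha_must_be_negative(self):
        with pytest.raises(ValueError):
            _cfg(alpha_ppm_per_C=0.01)

    def test_alpha_warning_band(self):
        with pytest.warns(UserWarning, match="alpha"):
            _cfg(alpha_ppm_per_C=-0.02)


class TestExactInversion:
    def test_noiseless_roundtrip_recovers_truth_to_machine_precision(
            self, ramp_hold_setup):
        """sigma=0, no drift: synthesize -> reconstruct equals truth exactly."""
        phantom, truth, meta, _ = ramp_hold_setup
        series = m.synthesize_series(phantom, truth, m.NoiseSpec(), meta)
        temps = m.reconstruct_series(series, _cfg())
        ok = ~np.isnan(temps.dT_C)
        assert np.max(np.abs(temps.dT_C[ok] - truth.dT_C[ok])) < 1e-9

    def test_alpha_sensitivity_scales_inversely(self, ramp_hold_setup):
        """Using alpha*(1+eps) in reconstruction scales dT by 1/(1+eps)."""
        phantom, truth, meta, _ = ramp_hold_setup
        series = m.synthesize_series(phantom, truth, m.NoiseSpec(), meta)
        t_true = m.reconstruct_series(series, _cfg())
        eps = 0.08
        t_bias = m.reconstruct_series(series, _cfg(alpha_ppm_per_C=-0.01 * (1 + eps)))
        ok = ~np.isnan(t_true.dT_C) & (np.abs(t_true.dT_C) > 0.5)
        ratio = t_bias.dT_C[ok] / t_true.dT_C[ok]
        np.testing.assert_allclose(ratio, 1 / (1 + eps), rtol=1e-9)
        rel_err = np.abs(t_bias.dT_C[ok] - t_true.dT_C[ok]) / np.abs(t_true.dT_C[ok])
        assert np.all(rel_err <= eps + 1e-9)

    def test_higher_field_means_larger_phase_shift(self, small_phantom):
        """The PRF frequency shift grows with B0 at fixed dT (1.5/3/7 T)."""
        shifts = []
        for b0 in (1.5, 3.0, 7.0):
            f0 = 42.577478518 * b0
            meta = m.AcquisitionMeta(TE_ms=10.0, TR_ms=400.0, FA_deg=13.0,
                                     B0_T=b0, f0_MHz=f0, FOV_mm=(32, 32),
                                     matrix=(32, 32), n_slices=1,
                                     timestamp_s=(0.0, 55.0))
            truth = m.GroundTruth.zeros(2, small_phantom.shape)
            truth.dT_C[1, 0, 16, 16] = 5.0
            series = m.synthesize_series(small_phantom, truth, m.NoiseSpec(),
                                         meta)
            dphi = np.angle(np.conj(series.data[0]) * series.data[1])
            shifts.append(abs(dphi[0, 16, 16]))
        assert shifts[0] < shifts[1] < shifts[2]


class TestDriftCorrect:
    def test_global_drift_removed(self, small_phantom):
        """5 Hz global drift with no heating: corrected map is ~zero."""
        meta = make_meta(2)
        truth = m.GroundTruth.zeros(2, small_phantom.shape)
        truth.drift_hz[1] = 5.0
        series = m.synthesize_series(small_phantom, truth, m.NoiseSpec(), meta)
        cfg = _cfg(drift_roi=m.Roi(0, 6, 9, 14, 18))
        temps = m.reconstruct_series(series, cfg)
        ok = ~np.isnan(temps.dT_C[1])
        np.testing.assert_allclose(temps.dT_C[1][ok], 0.0, atol=1e-9)

    def test_zero_drift_leaves_map_unchanged(self):
        rng = np.random.default_rng(0)
        dT = rng.normal(0, 0.1, (1, 16, 16))
        roi = m.Roi(0, 0, 4, 0, 4)
        dT[roi.mask(dT.shape)] = 0.0
        out = m.drift_correct(dT, roi)
        np.testing.assert_allclose(out, dT, atol=1e-12)

    def test_focal_estimate_unbiased_under_drift(self, small_phantom):
        """Drift + 3 °C focal heating: mean focal error ~0 over 20 seeds."""
        meta = make_meta(2)
        truth = m.GroundTruth.zeros(2, small_phantom.shape)
        truth.dT_C[1, 0, 16, 16] = 3.0
        truth.drift_hz[1] = 4.0
        errs = []
        for seed in range(20):
            series = m.synthesize_series(small_phantom, truth,
                                         m.NoiseSpec(sigma=0.003), meta,
                                         rng=seed)
            cfg = _cfg(drift_roi=m.Roi(0, 6, 9, 14, 18))
            temps = m.reconstruct_series(series, cfg)
            errs.append(temps.dT_C[1, 0, 16, 16] - 3.0)
        se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 3 * se + 0.02

    def test_drift_roi_overlapping_focus_rejected(self):
        dT = np.zeros((1, 16, 16))
        with pytest.raises(ValueError, match="overlap"):
            m.drift_correct(dT, m.Roi(0, 4, 8, 4, 8),
                            focus_roi=m.Roi(0, 6, 10, 6, 10))


class TestTemporalUnwrap:
    def test_monotone_ramp_crossing_minus_pi_is_continuous(self):
        """A ramp whose wrapped phase crosses -pi unwraps without sawtooth."""
        true_phase = -0.3 * np.arange(20)  # runs to -5.7 rad
        wrapped = (true_phase + np.pi) % (2 * np.pi) - np.pi
        unwrapped = m.temporal_unwrap(wrapped)
        np.testing.assert_allclose(unwrapped, true_phase, atol=1e-12)

    def test_constant_and_small_alternating_traces_unchanged(self):
        const = np.full(10, 0.4)
        np.testing.assert_allclose(m.temporal_unwrap(const), const)
        alt = 0.1 * (-1.0) ** np.arange(10)
        np.testing.assert_allclose(m.temporal_unwrap(alt), alt)

    def test_aliasing_step_flagged(self):
        with pytest.warns(UserWarning, match="aliasing"):
            m.temporal_unwrap(np.array([0.0, np.pi, 0.0]))


class TestHotspotTrace:
    def test_single_frame_series(self):
        temps = m.TemperatureSeries(times_s=np.array([0.0]),
                                    dT_C=np.zeros((1, 1, 4, 4)),
                                    valid=np.ones((1, 1, 4, 4), bool))
        trace = m.hotspot_trace(temps, voxel=(0, 1, 1))
        assert len(trace) == 1
        assert trace.temp_C[0] == 37.0

    def test_trace_matches_truth_within_noise(self, ramp_hold_setup):
        phantom, truth, meta, _ = ramp_hold_setup
        series = m.synthesize_series(phantom, truth, m.NoiseSpec(sigma=0.002),
                                     meta, rng=1)
        temps = m.reconstruct_series(series, _cfg())
        trace = m.hotspot_trace(temps, voxel=(0, 16, 16), absolute=False)
        np.testing.assert_allclose(trace.temp_C, truth.hotspot_trace(),
                                   atol=0.5)

    def test_cooling_decays_toward_baseline(self, small_phantom):
        """Frames after sonication stops decay monotonically to baseline."""
        n = 30
        meta = make_meta(n)
        params = m.calibrate()
        state = m.run_protocol(params, hold_s=600.0, cooldown_s=1200.0, rng=0)
        truth = m.heating_truth_from_bioheat(state, small_phantom, meta,
                                             (0, 16, 16))
        series = m.synthesize_series(small_phantom, truth, m.NoiseSpec(), meta)
        temps = m.reconstruct_series(series, _cfg())
        trace = m.hotspot_trace(temps, voxel=(0, 16, 16), absolute=False)
        cooling = trace.temp_C[meta.timestamp_s > np.asarray(720.0)]
        assert np.all(np.diff(cooling) < 0)
        # ~875 s of cooling with tau = 900 s: below 40% of the 8 °C rise
        assert cooling[-1] < 0.4 * 8.0

    def test_roi_mean_variant(self, ramp_hold_setup):
        phantom, truth, meta, _ = ramp_hold_setup
        series = m.synthesize_series(phantom, truth, m.NoiseSpec(), meta)
        temps = m.reconstruct_series(series, _cfg())
        trace = m.hotspot_trace(temps, roi=m.Roi(0, 15, 18, 15, 18),
                                absolute=False)
        assert trace.temp_C.max() < truth.hotspot_trace().max()
        # 3x3 ROI mean of the 1.5 mm kernel on a 1 mm grid: ~28% of the peak
        assert trace.temp_C.max() > 0.2 * truth.hotspot_trace().max()


class TestCompareToProbe:
    def test_worked_example_phantom(self):
        """Fiber optic 24.3 °C vs PRF 23.5 °C at the worst frame -> 0.8 °C."""
        t = np.array([0.0, 55.0, 110.0])
        probe = m.ProbeLog(t, np.array([20.0, 24.3, 22.0]))
        prf = m.ProbeLog(t, np.array([20.0, 23.5, 22.0]))
        comp = m.compare_to_probe(prf, probe)
        assert comp["max_abs_discrepancy_C"] == pytest.approx(0.8)
        assert comp["at_time_s"] == 55.0

    def test_worked_example_ex_vivo(self):
        """38.5 °C probe vs 37.5 °C PRF -> 1.0 °C max discrepancy."""
        t = np.array([0.0, 55.0])
        probe = m.ProbeLog(t, np.array([36.0, 38.5]))
        prf = m.ProbeLog(t, np.array([36.0, 37.5]))
        comp = m.compare_to_probe(prf, probe)
        assert comp["max_abs_discrepancy_C"] == pytest.approx(1.0)

    def test_identical_series_zero(self):
        t = np.arange(0, 500, 55.0)
        log = m.ProbeLog(t, 37.0 + 0.01 * t)
        comp = m.compare_to_probe(log, log)
        assert comp["max_abs_discrepancy_C"] == 0.0

    def test_no_overlap_rejected(self):
        a = m.ProbeLog(np.array([0.0, 10.0]), np.array([37.0, 38.0]))
        b = m.ProbeLog(np.array([100.0, 110.0]), np.array([37.0, 38.0]))
        with pytest.raises(ValueError, match="overlap"):
            m.compare_to_probe(a, b)
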