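"""Synthetic generator: signal model, forward phase model, noise statistics."""

import math

import numpy as np
import pytest

import mrgfus as m
from conftest import make_meta


class TestErnstAngle:
    def test_saturation_limit_is_90_degrees(self):
        assert m.ernst_angle(100 * 283.0, 283.0) == pytest.approx(90.0, abs=1e-6)

    def test_tr_equal_t1(self):
        # arccos(e^-1) by hand
        assert m.ernst_angle(283.0, 283.0) == pytest.approx(
            math.degrees(math.acos(math.exp(-1.0))), abs=1e-12)
        assert m.ernst_angle(283.0, 283.0) == pytest.approx(68.42, abs=0.01)

    def test_phantom_protocol_lands_in_12_to_14_degrees(self):
        """Short-TR FLASH on the agar phantom uses a 12-14 degree flip."""
        assert 12.0 <= m.ernst_angle(7.3, 283.0) <= 14.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            m.ernst_angle(0.0, 283.0)


class TestSpoiledGreSignal:
    def test_full_recovery_limit(self):
        meta = m.AcquisitionMeta(TE_ms=1e-9, TR_ms=50 * 283.0, FA_deg=90.0,
                                 B0_T=7.046, f0_MHz=300.0, FOV_mm=(32, 32),
                                 matrix=(32, 32))
        assert m.spoiled_gre_signal(3.0, 283.0, 60.0, meta) == pytest.approx(3.0)

    def test_te_equal_t2star_decays_by_e(self):
        meta1 = make_meta(1, te_ms=60.0)
        meta0 = make_meta(1, te_ms=1e-9)
        s1 = m.spoiled_gre_signal(1.0, 283.0, 60.0, meta1)
        s0 = m.spoiled_gre_signal(1.0, 283.0, 60.0, meta0)
        assert s1 / s0 == pytest.approx(math.exp(-1.0))

    def test_closed_form_hand_value(self):
        """PD=1, T1=283, T2*=60, TR=400, FA=30, TE=15 against scalar arithmetic."""
        meta = m.AcquisitionMeta(TE_ms=15.0, TR_ms=400.0, FA_deg=30.0,
                                 B0_T=7.046, f0_MHz=300.0, FOV_mm=(32, 32),
                                 matrix=(32, 32))
        e1 = math.exp(-400.0 / 283.0)
        expected = (math.sin(math.radians(30.0)) * (1 - e1)
                    / (1 - math.cos(math.radians(30.0)) * e1)
                    * math.exp(-15.0 / 60.0))
        assert m.spoiled_gre_signal(1.0, 283.0, 60.0, meta) == pytest.approx(
            expected, rel=1e-12)

    def test_rejects_bad_t2star(self, meta_300):
        with pytest.raises(ValueError):
            m.spoiled_gre_signal(1.0, 283.0, -5.0, meta_300)


class TestSynthesizeSeries:
    def test_no_perturbations_gives_phi0(self, small_phantom):
        meta = make_meta(2)
        truth = m.GroundTruth.zeros(2, small_phantom.shape)
        truth.phi0[:] = 0.3
        series = m.synthesize_series(small_phantom, truth, m.NoiseSpec(), meta)
        inside = small_phantom.label_map == 1
        assert np.allclose(series.phase[:, inside], 0.3)

    def test_single_hot_voxel_phase_shift(self, small_phantom):
        """1 °C at alpha=-0.01 ppm/°C, f0=300 MHz, TE=10 ms -> -0.1885 rad."""
        meta = make_meta(2)
        truth = m.GroundTruth.zeros(2, small_phantom.shape)
        truth.dT_C[1, 0, 16, 16] = 1.0
        series = m.synthesize_series(small_phantom, truth, m.NoiseSpec(), meta,
                                     alpha_ppm_per_C=-0.01)
        dphi = np.angle(np.conj(series.data[0]) * series.data[1])
        assert dphi[0, 16, 16] == pytest.approx(-0.18849556, abs=1e-6)
        assert dphi[0, 16, 17] == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_phase_difference_matches_forward_model_exactly(
            self, small_phantom):
        """sigma=0: frame-to-baseline phase equals 2*pi*(drift+alpha*f0*dT)*TE."""
        n = 4
        meta = make_meta(n)
        rng = np.random.default_rng(5)
        truth = m.GroundTruth.zeros(n, small_phantom.shape)
        truth.dT_C[1:] = rng.uniform(0, 3, truth.dT_C[1:].shape)
        truth.drift_hz[:] = [0.0, 1.0, -2.0, 0.5]
        truth.b0_offset_hz[:] = rng.uniform(-20, 20, small_phantom.shape)
        truth.phi0[:] = rng.uniform(-1, 1, small_phantom.shape)
        series = m.synthesize_series(small_phantom, truth, m.NoiseSpec(), meta)
        inside = small_phantom.label_map == 1
        te_s = meta.TE_ms * 1e-3
        for t in range(1, n):
            expected = 2 * np.pi * (truth.drift_hz[t]
                                    + (-0.01 * 300.0) * truth.dT_C[t]) * te_s
            dphi = np.angle(np.conj(series.data[0]) * series.data[t])
            np.testing.assert_allclose(dphi[inside], expected[inside],
                                       atol=1e-12)

    def test_seed_reproducibility(self, small_phantom):
        meta = make_meta(2)
        truth = m.GroundTruth.zeros(2, small_phantom.shape)
        a = m.synthesize_series(small_phantom, truth, m.NoiseSpec(sigma=1.0),
                                meta, rng=11)
        b = m.synthesize_series(small_phantom, truth, m.NoiseSpec(sigma=1.0),
                                meta, rng=11)
        c = m.synthesize_series(small_phantom, truth, m.NoiseSpec(sigma=1.0),
                                meta, rng=12)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        # noiseless component identical: denoise by averaging is not needed,
        # compare the difference structure instead
        clean = m.synthesize_series(small_phantom, truth, m.NoiseSpec(), meta)
        np.testing.assert_allclose(np.mean(np.abs(a.data - clean.data) ** 2),
                                   2.0, rtol=0.05)

    def test_background_magnitude_sd_is_rician(self, small_phantom):
        """Rayleigh background: SD(|noise|) = 0.655 * sigma over >=1e5 voxels."""
        shape = (1, 350, 350)
        phantom = m.PhantomSpec(np.zeros(shape, dtype=int),
                                {0: (0.0, 1.0, 1.0)})
        meta = make_meta(1, shape=shape)
        truth = m.GroundTruth.zeros(1, shape)
        series = m.synthesize_series(phantom, truth, m.NoiseSpec(sigma=1.0),
                                     meta, rng=0)
        sd = np.std(series.magnitude, ddof=1)
        assert sd == pytest.approx(0.6551, rel=0.01)

    def test_zipper_and_void_artifacts(self, small_phantom):
        meta = make_meta(1)
        truth = m.GroundTruth.zeros(1, small_phantom.shape)
        void = np.zeros(small_phantom.shape, bool)
        void[0, 28:, :] = True
        spec = m.NoiseSpec(sigma=0.0, zipper=True, zipper_amplitude=5.0,
                           void_mask=void)
        series = m.synthesize_series(small_phantom, truth, spec, meta)
        cols = spec.zipper_cols(32, small_phantom.voxel_spacing_mm[2])
        assert np.all(series.magnitude[0, 0, :10, cols] >= 5.0)  # background stripe
        assert np.all(series.magnitude[0, void] == 0.0)

    def test_sigma_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            m.NoiseSpec(sigma=-0.1)


class TestRicianMonteCarlo:
    def test_ratio_converges_to_0p655(self):
        ratio = m.rician_background_ratio(200_000, rng=123)
        assert ratio == pytest.approx(m.RICIAN_SD_FACTOR, rel=0.01)
        assert m.RICIAN_SD_FACTOR == pytest.approx(0.655, abs=5e-4)

    def test_scale_invariance_in_sigma(self):
        r1 = m.rician_background_ratio(50_000, sigma=1.0, rng=7)
        r2 = m.rician_background_ratio(50_000, sigma=12.5, rng=7)
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestHeatingTruthFromBioheat:
    def test_zero_trace_gives_zero_fields(self, small_phantom):
        meta = make_meta(3)
        state = m.ProtocolState(np.arange(200.0), np.full(200, 37.0),
                                np.zeros(200), np.array(["hold"] * 200, object))
        truth = m.heating_truth_from_bioheat(state, small_phantom, meta,
                                             (0, 16, 16))
        assert np.all(truth.dT_C == 0)

    def test_peak_voxel_tracks_trace(self, ramp_hold_setup):
        phantom, truth, meta, state = ramp_hold_setup
        expected = np.interp(meta.timestamp_s, state.time_s,
                             state.temp_C - state.temp_C[0])
        np.testing.assert_allclose(truth.dT_C[:, 0, 16, 16], expected,
                                   rtol=1e-12)

    def test_kernel_lateral_width_matches_config(self, ramp_hold_setup):
        """The -6 dB (half-max) width of the heat kernel is the focal width."""
        phantom, truth, meta, state = ramp_hold_setup
        profile = truth.dT_C[-1, 0, 16, :]
        axis_mm = np.arange(32) * phantom.voxel_spacing_mm[2]
        width_mm = m.fwhm_minus6db(axis_mm, profile)
        assert abs(width_mm - 1.5) <= phantom.voxel_spacing_mm[2]

    def test_focus_outside_grid_rejected(self, small_phantom):
        meta = make_meta(2)
        state = m.ProtocolState(np.arange(200.0), np.full(200, 37.0),
                                np.zeros(200), np.array(["hold"] * 200, object))
        with pytest.raises(ValueError, match="outside"):
            m.heating_truth_from_bioheat(state, small_phantom, meta, (0, 99, 16))
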