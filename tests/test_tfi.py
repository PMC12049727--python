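"""Thin-film interference model, trace fitting and per-pixel map fitting."""
import numpy as np
import pytest

from lamellometer import (
    TfiParams,
    ThicknessMap,
    fit_thickness_map,
    fit_trace,
    reflectivity,
    refractive_index_ice,
    uniformity_sigma,
)
from lamellometer.errors import AmbiguousOffsetError
from lamellometer.tfi import (
    _TABLE_TEMPERATURES_K,
    _TABLE_WAVELENGTHS_NM,
    _dispersion_table,
)


class TestRefractiveIndex:
    def test_anchor_value_mid_visible_cryo(self):
        assert refractive_index_ice(550.0, 109.0) == pytest.approx(1.28, abs=1e-3)

    def test_interpolation_identity_at_table_nodes(self):
        table = _dispersion_table()
        assert refractive_index_ice(
            _TABLE_WAVELENGTHS_NM[4], _TABLE_TEMPERATURES_K[1]
        ) == pytest.approx(table[4, 1], abs=1e-12)

    def test_interpolated_values_within_table_bounds(self):
        table = _dispersion_table()
        grid = [refractive_index_ice(lam, 115.0) for lam in np.linspace(420, 680, 27)]
        assert table.min() <= min(grid) and max(grid) <= table.max()

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning, match="extrapolat"):
            refractive_index_ice(900.0, 109.0)


class TestReflectivityModel:
    def test_zero_thickness_is_destructive_interference(self, tfi_params):
        assert reflectivity(0.0, tfi_params) == tfi_params.r_mea - tfi_params.r_A

    def test_quarter_wave_is_first_cosine_maximum(self):
        # dense-scan oracle on the undamped oscillation (L -> infinity):
        # the first local maximum sits at d = lambda/(4 n2), where the
        # cosine phase 4*pi*d*n2/lambda + pi completes half a turn
        params = TfiParams(wavelength_nm=463.0, L_nm=1e12)
        d_qw = params.wavelength_nm / (4 * params.n2)
        scan = np.arange(0.0, 150.0, 0.01)
        r = reflectivity(scan, params)
        peak = scan[1:-1][(r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])][0]
        assert peak == pytest.approx(d_qw, abs=0.05)

    def test_extrema_spacing_is_half_wavelength_in_film(self):
        # with the default exponential envelope the phase offset of each
        # extremum is a constant, so the peak spacing stays exactly at
        # P = lambda/(2 n2) (numerical peak-spacing oracle, 0.1 nm grid)
        params = TfiParams(wavelength_nm=463.0, envelope="exponential")
        scan = np.arange(0.0, 1200.0, 0.1)
        r = reflectivity(scan, params)
        maxima = scan[1:-1][(r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])]
        spacings = np.diff(maxima)
        assert np.all(np.abs(spacings - params.period_nm) < 0.5)

    def test_gaussian_envelope_keeps_period_when_decay_is_slow(self):
        params = TfiParams(wavelength_nm=463.0, envelope="gaussian", L_nm=1e6)
        scan = np.arange(0.0, 1200.0, 0.1)
        r = reflectivity(scan, params)
        maxima = scan[1:-1][(r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])]
        assert np.all(np.abs(np.diff(maxima) - params.period_nm) < 0.5)

    def test_large_thickness_relaxes_to_mean(self, tfi_params):
        assert reflectivity(1e5, tfi_params) == pytest.approx(tfi_params.r_mea, abs=1e-6)


class TestTraceFit:
    def _trace(self, tfi_params, offset=390.0, rate=2.4, t_max=200.0):
        ts = np.arange(0.0, t_max, 1.0)
        d = offset + rate * (ts[-1] - ts)
        return ts, reflectivity(d, tfi_params)

    def test_noiseless_offset_recovered_to_grid_resolution(self, tfi_params):
        ts, intensity = self._trace(tfi_params)
        fit = fit_trace(intensity, ts, 2.4, tfi_params, d_offset_search_nm=(200, 600))
        assert fit.offset_nm == pytest.approx(390.0, abs=1.0)

    def test_noisy_offset_recovered_within_10nm(self, tfi_params, rng):
        # 2% of the oscillation amplitude, offset search constrained by the
        # geometric estimate as in the milling workflow
        ts, intensity = self._trace(tfi_params)
        noisy = intensity + rng.normal(0, 0.02 * tfi_params.r_A, intensity.shape)
        fit = fit_trace(noisy, ts, 2.4, tfi_params, d_offset_search_nm=(300, 500))
        assert fit.offset_nm == pytest.approx(390.0, abs=10.0)

    def test_affine_intensity_invariance(self, tfi_params):
        ts, intensity = self._trace(tfi_params)
        f0 = fit_trace(intensity, ts, 2.4, tfi_params, d_offset_search_nm=(200, 600))
        f1 = fit_trace(5.0 * intensity + 3.0, ts, 2.4, tfi_params,
                       d_offset_search_nm=(200, 600))
        assert f1.offset_nm == pytest.approx(f0.offset_nm, abs=1e-9)

    def test_constant_trace_is_ambiguous(self, tfi_params):
        with pytest.raises(AmbiguousOffsetError):
            fit_trace(np.ones(100), np.arange(100.0), 2.4, tfi_params)

    def test_subperiod_trace_is_ambiguous(self, tfi_params):
        ts, intensity = self._trace(tfi_params, t_max=30.0)  # 72 nm < period
        with pytest.raises(AmbiguousOffsetError):
            fit_trace(intensity, ts, 2.4, tfi_params)


def _map_scene(tfi_params, rng, truth_center=188.0, snr=20.0, init_sigma=15.0):
    truth = truth_center + np.linspace(-10, 10, 64)[None, :] + np.zeros((64, 1))
    span = 400.0
    thicknesses = truth[None] + np.linspace(0, span, 168)[::-1, None, None]
    stack = reflectivity(thicknesses, tfi_params)
    amplitude = stack.max(axis=0) - stack.min(axis=0)
    clean = reflectivity(truth, tfi_params)
    noisy = clean + rng.normal(0, amplitude / snr)
    init = ThicknessMap(
        truth + rng.normal(0, init_sigma, truth.shape), 0.1, method="geometric"
    )
    return truth, span, stack, clean, noisy, init


class TestMapFit:
    def test_noiseless_exact_init_is_fixed_point(self, tfi_params, rng):
        truth, span, stack, clean, _noisy, _init = _map_scene(tfi_params, rng)
        exact_init = ThicknessMap(truth.copy(), 0.1, method="geometric")
        fitted = fit_thickness_map(
            clean, exact_init, tfi_params,
            norm_min=stack.min(axis=0), norm_max=stack.max(axis=0),
            norm_span_nm=span,
        )
        assert np.nanmax(np.abs(fitted.values_nm - truth)) < 1.0

    def test_noisy_recovery_mean_within_10nm(self, tfi_params, rng):
        truth, span, stack, _clean, noisy, init = _map_scene(tfi_params, rng)
        fitted = fit_thickness_map(
            noisy, init, tfi_params,
            norm_min=stack.min(axis=0), norm_max=stack.max(axis=0),
            norm_span_nm=span,
        )
        assert abs(np.nanmean(fitted.values_nm - truth)) < 10.0
        assert np.isfinite(fitted.metadata["uniformity_sigma_nm"])

    def test_init_off_by_one_period_aliases_by_one_period(self, tfi_params, rng):
        # documented branch-failure mode of the interference-order choice
        truth, span, stack, clean, _noisy, _init = _map_scene(tfi_params, rng)
        period = tfi_params.period_nm
        shifted = ThicknessMap(truth + period, 0.1, method="geometric")
        fitted = fit_thickness_map(
            clean, shifted, tfi_params,
            norm_min=stack.min(axis=0), norm_max=stack.max(axis=0),
            norm_span_nm=span,
        )
        err = np.nanmean(fitted.values_nm - truth)
        assert err == pytest.approx(period, abs=0.15 * period)

    def test_pixels_without_init_are_flagged_not_fitted(self, tfi_params, rng):
        truth, span, stack, clean, _noisy, _init = _map_scene(tfi_params, rng)
        holes = truth.copy()
        holes[10, 10] = np.nan
        init = ThicknessMap(holes, 0.1, method="geometric",
                            mask=np.isfinite(holes))
        fitted = fit_thickness_map(
            clean, init, tfi_params,
            norm_min=stack.min(axis=0), norm_max=stack.max(axis=0),
            norm_span_nm=span,
        )
        assert not fitted.mask[10, 10]
        assert np.isnan(fitted.values_nm[10, 10])

    def test_thick_lamella_not_fitted(self, tfi_params):
        init = ThicknessMap(np.full((4, 4), 2500.0), 0.1, method="geometric")
        fitted = fit_thickness_map(
            np.ones((4, 4)), init, tfi_params,
            norm_min=np.zeros((4, 4)), norm_max=np.ones((4, 4)),
        )
        assert not fitted.mask.any()


class TestUniformitySigma:
    def test_constant_map_has_zero_sigma(self):
        tmap = ThicknessMap(np.full((8, 8), 188.0), 0.1)
        assert uniformity_sigma(tmap) == 0.0

    def test_three_level_map_closed_form(self):
        values = np.repeat([180.0, 190.0, 200.0], 3).reshape(3, 3).T
        tmap = ThicknessMap(values, 0.1)
        assert uniformity_sigma(tmap) == pytest.approx(np.sqrt(200.0 / 3.0), rel=1e-12)

    def test_injected_noise_sigma_recovered(self, rng):
        values = 188.0 + rng.normal(0, 5.0, (64, 64))
        tmap = ThicknessMap(values, 0.1)
        # sampling error of an SD estimate: sigma/sqrt(2(n-1))
        se = 5.0 / np.sqrt(2 * (values.size - 1))
        assert uniformity_sigma(tmap) == pytest.approx(5.0, abs=4 * se)

    def test_empty_roi_raises(self):
        tmap = ThicknessMap(np.ones((4, 4)), 0.1)
        with pytest.raises(ValueError, match="empty"):
            uniformity_sigma(tmap, roi=np.zeros((4, 4), dtype=bool))
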