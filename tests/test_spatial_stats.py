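"""Semivariograms, spherical fits, radial spectra, and gamma calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tikscape import (
    FieldSpec,
    FitError,
    RasterGrid,
    Semivariogram,
    build_calibration_curve,
    calibrate_gamma,
    empirical_semivariogram,
    ensemble_range_statistics,
    fit_spherical,
    radial_power_spectrum,
    spherical_model,
)


def brute_force_matheron(grid: RasterGrid, max_lag: float, bin_width: float):
    """All-pairs Matheron estimator, the independent oracle for small grids."""
    z = grid.values
    n_rows, n_cols = z.shape
    px = grid.pixel_size
    sums, counts = {}, {}
    cells = [(i, j) for i in range(n_rows) for j in range(n_cols)]
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            (i1, j1), (i2, j2) = cells[a], cells[b]
            d = np.hypot(i1 - i2, j1 - j2) * px
            if d > max_lag:
                continue
            k = max(1, int(np.floor(d / bin_width + 0.5)))
            sums[k] = sums.get(k, 0.0) + (z[i1, j1] - z[i2, j2]) ** 2
            counts[k] = counts.get(k, 0) + 1
    ks = sorted(counts)
    return np.array([sums[k] / (2 * counts[k]) for k in ks]), np.array(
        [counts[k] for k in ks]
    )


class TestEmpiricalSemivariogram:
    def test_two_pixel_hand_value(self):
        """1x2 grid with values {0, 1}: gamma_hat = (1-0)^2 / (2*1) = 0.5."""
        grid = RasterGrid(np.array([[0.0, 1.0]]), pixel_size=1.0)
        sv = empirical_semivariogram(grid, max_lag=1.5, bin_width=1.0)
        assert sv.n_bins == 1
        np.testing.assert_allclose(sv.gamma_hat, [0.5])
        np.testing.assert_array_equal(sv.pair_counts, [1])

    def test_constant_field_is_zero(self):
        grid = RasterGrid(np.full((5, 5), 0.54), pixel_size=4.0)
        sv = empirical_semivariogram(grid)
        np.testing.assert_array_equal(sv.gamma_hat, 0.0)

    @pytest.mark.parametrize("dims", [(2, 3), (4, 4), (6, 6), (3, 6)])
    def test_matches_all_pairs_brute_force(self, dims, rng):
        """The lattice-offset computation is exactly the all-pairs estimator."""
        grid = RasterGrid(rng.normal(size=dims), pixel_size=2.0)
        max_lag = max(dims) * 2.0  # include every pair
        sv = empirical_semivariogram(grid, max_lag=max_lag, bin_width=2.0)
        g_ref, n_ref = brute_force_matheron(grid, max_lag, 2.0)
        np.testing.assert_allclose(sv.gamma_hat, g_ref, atol=1e-12)
        np.testing.assert_array_equal(sv.pair_counts, n_ref)

    def test_white_noise_flat_at_variance(self, rng):
        """Semivariance of i.i.d. data equals its variance at every lag."""
        v = 0.25
        grid = RasterGrid(rng.normal(0, np.sqrt(v), (50, 50)), pixel_size=1.0)
        sv = empirical_semivariogram(grid)
        np.testing.assert_allclose(sv.gamma_hat, v, rtol=0.12)

    def test_lag_centers_strictly_increasing(self, small_field):
        sv = empirical_semivariogram(small_field)
        assert np.all(np.diff(sv.lag_centers) > 0)
        assert np.all(sv.pair_counts > 0)

    def test_default_max_lag_is_half_longer_side(self, small_field):
        sv = empirical_semivariogram(small_field)
        assert sv.lag_centers[-1] <= 0.5 * 24 * 4.0


class TestFitSpherical:
    def test_exact_recovery_of_noise_free_model(self):
        """Fitting a noise-free spherical curve recovers (c0, c, a) to 1e-6."""
        h = np.arange(4.0, 125.0, 4.0)
        g = spherical_model(h, 0.002, 0.007, 48.0)
        sv = Semivariogram(h, g, np.full(h.size, 100, dtype=int))
        fit = fit_spherical(sv)
        np.testing.assert_allclose(
            [fit.nugget, fit.partial_sill, fit.range_m], [0.002, 0.007, 48.0],
            atol=1e-6,
        )
        assert fit.converged and fit.identifiable

    def test_constrained_fit_pins_total_sill(self):
        h = np.arange(4.0, 125.0, 4.0)
        g = spherical_model(h, 0.002, 0.007, 48.0)
        sv = Semivariogram(h, g, np.full(h.size, 100, dtype=int))
        fit = fit_spherical(sv, total_sill=0.009)
        np.testing.assert_allclose(fit.total_sill, 0.009, atol=1e-12)
        np.testing.assert_allclose(fit.range_m, 48.0, atol=1e-4)

    def test_flat_semivariogram_raise_or_flag(self):
        h = np.arange(1.0, 6.0)
        sv = Semivariogram(h, np.zeros(5), np.full(5, 10, dtype=int))
        with pytest.raises(FitError, match="unidentifiable"):
            fit_spherical(sv)
        flagged = fit_spherical(sv, on_flat="flag")
        assert not flagged.identifiable
        assert flagged.range_m == h[0]

    def test_too_few_bins_rejected(self):
        sv = Semivariogram([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], [5, 5, 5])
        with pytest.raises(ValueError, match="4"):
            fit_spherical(sv)

    def test_range_may_exceed_max_lag(self):
        """A variogram still rising at the last lag fits a range beyond it."""
        h = np.arange(4.0, 125.0, 4.0)
        g = spherical_model(h, 0.0, 0.009, 160.0)
        sv = Semivariogram(h, g, np.full(h.size, 100, dtype=int))
        fit = fit_spherical(sv, total_sill=0.009)
        assert fit.range_m > h[-1]
        np.testing.assert_allclose(fit.range_m, 160.0, rtol=1e-3)


class TestRadialSpectrum:
    def test_constant_field_zero_power(self):
        grid = RasterGrid(np.full((8, 8), 0.54), pixel_size=4.0)
        spec = radial_power_spectrum(grid)
        np.testing.assert_allclose(spec.power, 0.0, atol=1e-20)

    def test_pure_cosine_dominant_annulus(self):
        """A cosine of wavelength 32 pixels concentrates power at 1/(32 px)."""
        px = 4.0
        n = 64
        x = np.arange(n)
        z = np.cos(2 * np.pi * x[None, :] / 32.0) * np.ones((n, 1))
        spec = radial_power_spectrum(RasterGrid(z, pixel_size=px))
        dominant = spec.frequencies[np.argmax(spec.power)]
        np.testing.assert_allclose(dominant, 1.0 / (32.0 * px), rtol=1e-6)

    def test_parseval_total_power_equals_variance(self, small_field):
        """Power summed over all nonzero-frequency coefficients equals the
        field's population variance (direct-summation oracle)."""
        spec = radial_power_spectrum(small_field)
        np.testing.assert_allclose(spec.total_power, small_field.var(), rtol=1e-10)
        # independent direct summation
        z = small_field.values
        F = np.fft.fft2(z - z.mean())
        np.testing.assert_allclose(
            np.sum(np.abs(F) ** 2) / z.size**2, spec.total_power, rtol=1e-10
        )

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="4x4"):
            radial_power_spectrum(RasterGrid(np.ones((3, 5)), pixel_size=1.0))

    def test_smoothed_ensemble_peaks_at_long_wavelengths(self, tundra_spec):
        """Fields at the calibrated multiplier concentrate power above 40 m
        wavelength (one dominant low-frequency mode)."""
        from tikscape import generate_fields

        spec = tundra_spec.with_gamma(10**0.85)
        rng = np.random.default_rng(2)
        total = None
        for grid in generate_fields(spec, 20, rng=rng):
            s = radial_power_spectrum(grid)
            total = s.power if total is None else total + s.power
        peak_wavelength = 1.0 / s.frequencies[np.argmax(total)]
        assert peak_wavelength > 40.0


@pytest.fixture(scope="module")
def curve():
    template = FieldSpec(40, 40, pixel_size=4.0, gamma=1.0)
    return build_calibration_curve(
        template, [-1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0], n_iter=20,
        rng=np.random.default_rng(31),
    )


class TestCalibration:
    def test_fitted_curve_tracks_recorded_means(self, curve):
        predicted = curve.predict(curve.log10_gamma)
        resid = np.abs(predicted - curve.mean_range)
        assert np.all(resid < np.maximum(2.0 * curve.sd_range, 5.0))

    def test_monotone_in_gamma(self, curve):
        assert curve.mean_range[-1] > curve.mean_range[0]
        xs = np.linspace(-1.5, 2.5, 100)
        assert np.all(np.diff(curve.predict(xs)) >= -1e-9)

    def test_inversion_monotone_and_consistent(self, curve):
        lo = calibrate_gamma(curve, 20.0)
        hi = calibrate_gamma(curve, 60.0)
        assert hi > lo
        np.testing.assert_allclose(
            curve.predict(np.log10(calibrate_gamma(curve, 40.0))), 40.0, rtol=1e-8
        )

    def test_target_outside_asymptotes_rejected(self, curve):
        with pytest.raises(ValueError, match="achievable"):
            calibrate_gamma(curve, curve.upper_asymptote * 2.0)
        with pytest.raises(ValueError, match="achievable"):
            calibrate_gamma(curve, 0.0)

    def test_round_trip_recovers_gamma(self, curve):
        """Pick gamma* = 5, measure its ensemble mean range, calibrate back:
        the recovered multiplier is within 25% (simulation round trip)."""
        template = FieldSpec(40, 40, pixel_size=4.0, gamma=1.0)
        stats = ensemble_range_statistics(
            template, 5.0, 30, rng=np.random.default_rng(8)
        )
        recovered = calibrate_gamma(curve, stats.mean_range)
        assert abs(recovered - 5.0) / 5.0 < 0.25

    def test_too_few_grid_points_rejected(self):
        template = FieldSpec(10, 10, gamma=1.0)
        with pytest.raises(ValueError, match="4"):
            build_calibration_curve(template, [0.0, 1.0], 5)


class TestEnsembleStats:
    def test_monotone_smoothing(self):
        """Mean fitted range is non-decreasing in the multiplier."""
        template = FieldSpec(32, 32, pixel_size=4.0, gamma=1.0)
        rng = np.random.default_rng(17)
        means = [
            ensemble_range_statistics(template, g, 25, rng=rng).mean_range
            for g in (0.1, 1.0, 10.0, 100.0)
        ]
        assert np.all(np.diff(means) > 0)

    def test_total_sill_tracks_target_variance(self):
        """Across multipliers, mean(nugget + partial sill) stays within 15%
        of the target variance 0.009."""
        template = FieldSpec(32, 32, pixel_size=4.0, gamma=1.0)
        rng = np.random.default_rng(23)
        for g in (0.1, 1.0, 10.0, 100.0):
            stats = ensemble_range_statistics(template, g, 15, rng=rng)
            total = stats.mean_nugget + stats.mean_partial_sill
            assert abs(total - 0.009) / 0.009 < 0.15


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    n_rows=st.integers(2, 6),
    n_cols=st.integers(2, 6),
    seed=st.integers(0, 2**31 - 1),
)
def test_matheron_brute_force_property(n_rows, n_cols, seed):
    """Offset-based estimator equals the all-pairs oracle on any small grid."""
    if n_rows * n_cols < 2:
        return
    values = np.random.default_rng(seed).uniform(0, 1, (n_rows, n_cols))
    grid = RasterGrid(values, pixel_size=3.0)
    max_lag = 3.0 * max(n_rows, n_cols)
    sv = empirical_semivariogram(grid, max_lag=max_lag, bin_width=3.0)
    g_ref, n_ref = brute_force_matheron(grid, max_lag, 3.0)
    np.testing.assert_allclose(sv.gamma_hat, g_ref, atol=1e-12)
    np.testing.assert_array_equal(sv.pair_counts, n_ref)
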