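import numpy as np
import pytest

from retscat.config import OpticalConfig
from retscat.correlation import (CorrelationCurve, CorrelationMap,
                                 angular_to_correlation, azimuthal_integrate,
                                 fit_slope, long_range_slope)
from retscat.layers import AngularPlaneWithMask
from retscat.synthetic import MediumSpec, make_angular_plane


def _brute_force_map(plane):
    """O(n^4) centered DFT magnitude, written directly from the double sum."""
    n_x, n_y = plane.shape
    out = np.zeros((n_x, n_y), complex)
    xs = np.arange(n_x)
    ys = np.arange(n_y)
    for u in range(n_x):
        for v in range(n_y):
            ph = np.exp(-2j * np.pi * (np.add.outer(u * xs / n_x, v * ys / n_y)))
            out[u, v] = np.sum(plane * ph)
    return np.abs(np.fft.fftshift(out))


class TestAngularToCorrelation:
    def test_matches_brute_force_double_sum(self, rng):
        cfg = OpticalConfig(n_theta_x=16, n_theta_y=16)
        plane = rng.random((16, 16))
        corr = angular_to_correlation(plane, cfg)
        assert np.allclose(corr.values, _brute_force_map(plane), rtol=1e-9, atol=1e-9)

    def test_uniform_plane_is_pure_zero_lag(self, cfg):
        corr = angular_to_correlation(np.full((128, 128), 2.0), cfg)
        curve = azimuthal_integrate(corr)
        assert corr.values[corr.zero_index] == pytest.approx(2.0 * 128 * 128)
        assert np.allclose(curve.energy, 0.0, atol=1e-6)

    def test_zero_lag_equals_total_power(self, cfg, rng):
        plane = rng.random((128, 128))
        corr = angular_to_correlation(plane, cfg)
        assert corr.values[corr.zero_index] == pytest.approx(abs(plane.sum()), rel=1e-9)

    def test_gaussian_conjugate_width(self, cfg):
        # angular Gaussian sigma = 10 px -> correlation Gaussian sigma = n/(2 pi 10)
        n = 128
        x = np.arange(n) - n / 2
        plane = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / (2 * 10.0**2))
        corr = angular_to_correlation(plane, cfg)
        zi, zj = corr.zero_index
        row = corr.values[:, zj]
        sel = (np.abs(corr.lag_x) > 0) & (np.abs(corr.lag_x) <= 6.0)
        # log v = c - lag^2 / (2 sigma^2): recover sigma from a linear fit
        coef = np.polyfit(corr.lag_x[sel] ** 2, np.log(row[sel]), 1)
        sigma_hat = np.sqrt(-1.0 / (2 * coef[0]))
        assert sigma_hat == pytest.approx(n / (2 * np.pi * 10.0), rel=0.02)

    def test_point_reflection_symmetry(self, cfg, rng):
        # real input: |F(k)| = |F(-k)|
        corr = angular_to_correlation(rng.random((128, 128)), cfg)
        v = corr.values
        assert np.allclose(v, np.roll(v[::-1, ::-1], (1, 1), axis=(0, 1)), rtol=1e-12)

    def test_masked_pixels_are_median_filled(self, cfg, rng):
        data = rng.random((32, 32))
        mask = np.zeros((32, 32), bool)
        mask[0, :5] = True
        filled = data.copy()
        filled[mask] = np.median(data[~mask])
        small = OpticalConfig(n_theta_x=32, n_theta_y=32)
        c1 = angular_to_correlation(AngularPlaneWithMask(intensity=data, mask=mask), small)
        c2 = angular_to_correlation(filled, small)
        assert np.array_equal(c1.values, c2.values)

    def test_fully_masked_plane_rejected(self, cfg):
        apm = AngularPlaneWithMask(intensity=np.ones((8, 8)),
                                   mask=np.ones((8, 8), bool))
        with pytest.raises(ValueError, match="retained"):
            angular_to_correlation(apm, cfg)

    def test_nonfinite_plane_rejected(self, cfg):
        plane = np.ones((16, 16))
        plane[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            angular_to_correlation(plane, cfg)


class TestAzimuthalIntegrate:
    def test_matches_brute_force_binning(self, cfg, rng):
        corr = angular_to_correlation(rng.random((64, 64)), cfg)
        curve = azimuthal_integrate(corr)
        r = corr.radius_grid()
        zi = corr.zero_index
        for i, center in enumerate(curve.lag):
            lo, hi = center - 0.5, center + 0.5
            sel = (r >= lo) & (r < hi)
            sel[zi] = False
            assert curve.counts[i] == sel.sum()
            assert curve.energy[i] == pytest.approx(corr.values[sel].sum(), rel=1e-12)

    def test_ring_impulse_lands_in_one_bin(self, cfg):
        n = 64
        lag = (np.arange(n) - n // 2) * 1.0
        vals = np.zeros((n, n))
        r = np.hypot(lag[:, None], lag[None, :])
        ring = (r >= 5.0) & (r < 6.0)
        vals[ring] = 1.0
        curve = azimuthal_integrate(CorrelationMap(vals, lag, lag))
        assert curve.energy[np.argmax(curve.energy)] == pytest.approx(ring.sum())
        assert curve.lag[np.argmax(curve.energy)] == pytest.approx(5.5)
        assert curve.energy.sum() == pytest.approx(ring.sum())

    def test_rotation_invariance(self, cfg, rng):
        plane = rng.random((128, 128))
        c1 = azimuthal_integrate(angular_to_correlation(plane, cfg))
        c2 = azimuthal_integrate(angular_to_correlation(np.rot90(plane), cfg))
        assert np.allclose(c1.energy, c2.energy, rtol=1e-9)

    def test_total_energy_conserved(self, cfg, rng):
        corr = angular_to_correlation(rng.random((64, 64)), cfg)
        curve = azimuthal_integrate(corr)
        expected = corr.values.sum() - corr.values[corr.zero_index]
        assert curve.energy.sum() == pytest.approx(expected, rel=1e-12)

    def test_bin_width_below_pixel_rejected(self, cfg, rng):
        corr = angular_to_correlation(rng.random((32, 32)), cfg)
        with pytest.raises(ValueError, match="bin_width"):
            azimuthal_integrate(corr, bin_width=0.5)


class TestFitSlope:
    def _curve(self, fn, r_max=64.0):
        lag = np.arange(0.5, r_max, 1.0)
        return CorrelationCurve(lag=lag, energy=fn(lag), counts=np.ones_like(lag))

    def test_exact_inverse_law_gives_alpha_one(self):
        fit = fit_slope(self._curve(lambda r: 10.0 / r))
        assert fit.alpha == pytest.approx(1.0, abs=1e-9)
        assert fit.fd == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_curve_gives_alpha_zero(self):
        fit = fit_slope(self._curve(lambda r: np.full_like(r, 3.0)))
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)
        assert fit.fd == pytest.approx(3.0, abs=1e-12)

    def test_fd_identity_is_exact(self):
        for a in (0.0, 0.4, 1.3, 2.9):
            fit = fit_slope(self._curve(lambda r: r**-a))
            assert fit.fd == 3.0 - fit.alpha  # exact float identity

    def test_closed_loop_alpha_recovery(self, cfg):
        vals = []
        for seed in range(10):
            plane = make_angular_plane(MediumSpec(alpha_true=0.8, seed=seed), cfg)
            curve = azimuthal_integrate(angular_to_correlation(plane, cfg))
            vals.append(fit_slope(curve).alpha)
        assert 0.72 <= np.mean(vals) <= 0.88

    def test_broken_power_law_resolved_by_window(self):
        def broken(r):
            short = r**-0.5
            long = (10.0**-0.5) * (r / 10.0) ** -2.0
            return np.where(r < 10.0, short, long)

        curve = self._curve(broken)
        assert fit_slope(curve, window=(2, 9.5)).alpha == pytest.approx(0.5, abs=1e-9)
        assert long_range_slope(curve, window=(20, 60)).alpha == pytest.approx(
            2.0, abs=1e-9)

    def test_window_beyond_max_lag_names_geometry(self, cfg, rng):
        curve = azimuthal_integrate(angular_to_correlation(rng.random((32, 32)), cfg))
        with pytest.raises(ValueError, match="max lag"):
            fit_slope(curve, window=(100.0, 200.0))

    def test_scale_equivariance(self, cfg, rng):
        plane = rng.random((64, 64)) + 0.5
        f1 = fit_slope(azimuthal_integrate(angular_to_correlation(plane, cfg)))
        f2 = fit_slope(azimuthal_integrate(angular_to_correlation(7.0 * plane, cfg)))
        assert f2.alpha == pytest.approx(f1.alpha, abs=1e-12)
        assert f2.intercept - f1.intercept == pytest.approx(np.log10(7.0), abs=1e-10)

    def test_summary_mentions_alpha_and_fd(self):
        fit = fit_slope(self._curve(lambda r: 1.0 / r))
        s = fit.summary()
        assert "alpha" in s and "FD" in s
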