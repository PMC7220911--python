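"""Two-point spatial correlation and power-law (fractal) slope analysis.

The Fourier transform of a 2D angular scattering distribution yields the
two-point spatial correlation of the optical field. For tissue without a
preferred direction the 2D correlation is azimuthally integrated into a
radial correlation-energy curve; over a window of length scales the curve is
close to a power law C(r) ~ r^(-alpha), and the negative log-log slope alpha
is related to the fractal dimension of the medium by FD = 3 - alpha. The
short-range window (2-10 um by default) probes cellular and sub-cellular
texture; a long-range window is available for larger-scale organization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import OpticalConfig
from .layers import AngularPlaneWithMask

__all__ = [
    "CorrelationMap",
    "CorrelationCurve",
    "SlopeFit",
    "angular_to_correlation",
    "azimuthal_integrate",
    "fit_slope",
    "long_range_slope",
    "SHORT_RANGE_WINDOW",
    "LONG_RANGE_WINDOW",
]

SHORT_RANGE_WINDOW = (2.0, 10.0)
LONG_RANGE_WINDOW = (20.0, 100.0)


@dataclass
class CorrelationMap:
    """Magnitude of the 2D spatial correlation over (x-lag, y-lag).

    Lag axes are in micrometres with pixel size dr = lambda / theta_span;
    the zero-lag pixel sits at index (n_x // 2, n_y // 2).
    """

    values: np.ndarray
    lag_x: np.ndarray
    lag_y: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lag_x = np.asarray(self.lag_x, dtype=float)
        self.lag_y = np.asarray(self.lag_y, dtype=float)
        if self.values.shape != (len(self.lag_x), len(self.lag_y)):
            raise ValueError("values shape must match lag axes")

    @property
    def zero_index(self) -> tuple[int, int]:
        return int(np.argmin(np.abs(self.lag_x))), int(np.argmin(np.abs(self.lag_y)))

    def radius_grid(self) -> np.ndarray:
        """Radial lag |r| (um) of every pixel."""
        return np.hypot(self.lag_x[:, None], self.lag_y[None, :])


@dataclass
class CorrelationCurve:
    """Azimuthally integrated radial correlation energy.

    ``energy[i]`` is the sum (integration, not mean) of correlation magnitude
    over the annulus of radial lags [lag[i] - w/2, lag[i] + w/2), and
    ``counts[i]`` the number of lag pixels in that annulus.
    """

    lag: np.ndarray
    energy: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        self.counts = np.asarray(self.counts)
        if not np.all(np.diff(self.lag) > 0):
            raise ValueError("lag bin centers must be strictly increasing")
        if np.any(self.energy < 0):
            raise ValueError("correlation energies must be nonnegative")


@dataclass(frozen=True)
class SlopeFit:
    """Least-squares log-log power-law fit of a correlation curve.

    ``alpha`` is the negative slope of log10(energy) vs log10(lag) within
    the fit window; positive alpha means decaying correlation. The fractal
    dimension is the derived quantity FD = 3 - alpha.
    """

    alpha: float
    intercept: float
    window: tuple[float, float]
    r_squared: float
    n_points: int

    @property
    def fd(self) -> float:
        """Fractal dimension, FD = 3 - alpha (exact by construction)."""
        return 3.0 - self.alpha

    def summary(self) -> str:
        lo, hi = self.window
        return (
            f"power-law fit on [{lo:g}, {hi:g}] um: alpha = {self.alpha:.4f}, "
            f"FD = {self.fd:.4f}, R^2 = {self.r_squared:.4f} ({self.n_points} bins)"
        )


def angular_to_correlation(
    plane: AngularPlaneWithMask | np.ndarray,
    cfg: OpticalConfig,
    fill: str = "median",
) -> CorrelationMap:
    """Transform an angular scattering plane into its 2D spatial correlation.

    Returns the magnitude of the centered 2D discrete Fourier transform of
    the (mask-filled) plane; lag axes follow the small-angle conversion
    dr = lambda / theta_span.

    Excluded pixels are replaced by the median of the retained pixels
    (``fill="median"``, the default — avoids the spectral leakage a hard
    zero hole would cause) or by zero (``fill="zero"``).
    """
    if isinstance(plane, AngularPlaneWithMask):
        data = plane.intensity.copy()
        mask = plane.mask
        if mask.all():
            raise ValueError("plane has no retained pixels")
        if mask.any():
            if fill == "median":
                data[mask] = np.median(data[~mask])
            elif fill == "zero":
                data[mask] = 0.0
            else:
                raise ValueError(f"unknown fill mode {fill!r}")
    else:
        data = np.asarray(plane, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("plane must be finite")
    n_x, n_y = data.shape
    corr = np.abs(np.fft.fftshift(np.fft.fft2(data)))
    dr = cfg.lag_pixel
    lag_x = (np.arange(n_x) - n_x // 2) * dr
    lag_y = (np.arange(n_y) - n_y // 2) * dr
    return CorrelationMap(values=corr, lag_x=lag_x, lag_y=lag_y)


def azimuthal_integrate(corr: CorrelationMap, bin_width: float | None = None) -> CorrelationCurve:
    """Integrate the correlation map over annuli of radial lag.

    Each annulus [r_i, r_i + bin_width) accumulates the *sum* of correlation
    magnitudes of its pixels (azimuthal integration, not averaging). The
    zero-lag pixel — total power, not texture — is excluded. Empty annuli
    are dropped.
    """
    dr = float(np.min(np.abs(np.diff(corr.lag_x))))
    if bin_width is None:
        bin_width = dr
    if bin_width < dr - 1e-12:
        raise ValueError(f"bin_width {bin_width} is below the lag pixel size {dr}")
    r = corr.radius_grid()
    vals = corr.values.copy()
    zi = corr.zero_index
    keep = np.ones(vals.shape, dtype=bool)
    keep[zi] = False
    r_flat = r[keep]
    v_flat = vals[keep]
    n_bins = int(np.ceil(r_flat.max() / bin_width)) + 1
    idx = np.floor(r_flat / bin_width).astype(int)
    energy = np.bincount(idx, weights=v_flat, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    nz = counts > 0
    return CorrelationCurve(lag=centers[nz], energy=energy[nz], counts=counts[nz])


def fit_slope(curve: CorrelationCurve, window: tuple[float, float] = SHORT_RANGE_WINDOW) -> SlopeFit:
    """Fit the log-log power-law slope of a correlation curve over a window.

    Ordinary least squares of log10(energy) on log10(lag) restricted to bin
    centers inside [r_lo, r_hi]; at least 4 positive-energy bins are
    required. Returns alpha = -slope (FD = 3 - alpha is a derived property
    of the fit object).
    """
    r_lo, r_hi = window
    sel = (curve.lag >= r_lo) & (curve.lag <= r_hi) & (curve.energy > 0)
    n = int(sel.sum())
    if n < 4:
        dr = float(np.min(np.diff(curve.lag))) if len(curve.lag) > 1 else float("nan")
        raise ValueError(
            f"only {n} usable correlation bins inside window [{r_lo}, {r_hi}] um "
            f"(lag spacing {dr:g} um, max lag {curve.lag.max():g} um); need >= 4"
        )
    x = np.log10(curve.lag[sel])
    y = np.log10(curve.energy[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return SlopeFit(
        alpha=float(-slope), intercept=float(intercept), window=(r_lo, r_hi),
        r_squared=r2, n_points=n,
    )


def long_range_slope(curve: CorrelationCurve, window: tuple[float, float] = LONG_RANGE_WINDOW) -> SlopeFit:
    """Power-law slope over the long-range window (20-100 um by default)."""
    return fit_slope(curve, window=window)
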