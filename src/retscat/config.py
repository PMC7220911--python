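"""Optical and acquisition configuration shared by the generator and the analyzer.

A single small-angle coordinate convention links the angular and spatial-lag
domains: an angle theta maps to the transverse spatial frequency
q = (2*pi/lambda) * theta, so the discrete Fourier transform of an angular
scattering plane sampled over a total span ``theta_span`` (radians, per axis)
yields spatial lags sampled at

    dr    = lambda / theta_span          (lag-pixel size, micrometres)
    r_max = (n_theta // 2) * dr          (largest on-axis lag)

Both the synthetic-data generator and the correlation analyzer use this one
convention; there is no second coordinate system anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

LAYERS = ("NFL", "OPL", "RPE")
QUADRANTS = ("superior", "inferior", "nasal", "temporal")


class ConfigurationError(ValueError):
    """Raised when an optical configuration cannot support the requested analysis."""


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of the synthetic a/LCI + OCT acquisition.

    Parameters
    ----------
    center_wavelength : float
        Source center wavelength in micrometres (Ti:Sapphire, 0.830 um).
    n_wavenumber_samples : int
        Spectral samples per raw scan; the one-sided depth axis has half as
        many pixels.
    n_theta_x, n_theta_y : int
        Angular samples per axis of the 2D scattering plane.
    theta_span : float
        Total angular span per axis in radians. The default 0.830 rad gives
        a lag-pixel size of exactly 1.0 um for the default wavelength; the
        span is chosen for lag-domain sampling rather than to mimic the
        physical collection aperture.
    alci_pixel_to_depth : float
        Depth extent of one a/LCI transform pixel (um/px). The default 10
        matches a low-coherence axial resolution of roughly 10 um.
    oct_axial_pixel : float
        OCT B-scan axial pixel size (um/px).
    """

    center_wavelength: float = 0.830
    n_wavenumber_samples: int = 64
    n_theta_x: int = 128
    n_theta_y: int = 128
    theta_span: float = 0.830
    alci_pixel_to_depth: float = 10.0
    oct_axial_pixel: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_wavenumber_samples", "n_theta_x", "n_theta_y"):
            if getattr(self, name) < 8:
                raise ConfigurationError(f"{name} must be >= 8, got {getattr(self, name)}")
        if self.theta_span <= 0:
            raise ConfigurationError("theta_span must be positive")
        if self.center_wavelength <= 0:
            raise ConfigurationError("center_wavelength must be positive")
        if self.alci_pixel_to_depth <= 0 or self.oct_axial_pixel <= 0:
            raise ConfigurationError("pixel-to-depth factors must be positive")

    @property
    def lag_pixel(self) -> float:
        """Spatial-lag sampling interval dr = lambda / theta_span (um)."""
        return self.center_wavelength / self.theta_span

    @property
    def max_lag(self) -> float:
        """Largest on-axis lag r_max (um); radial lags reach sqrt(2) further."""
        return (min(self.n_theta_x, self.n_theta_y) // 2) * self.lag_pixel

    @property
    def n_depth(self) -> int:
        """Depth pixels of the one-sided spectral transform."""
        return self.n_wavenumber_samples // 2

    @property
    def max_depth(self) -> float:
        """Largest unambiguous depth (um) a raw scan can encode."""
        return (self.n_depth - 1) * self.alci_pixel_to_depth

    def validate_fit_window(self, window: tuple[float, float], min_samples: int = 8) -> None:
        """Check that a radial fit window is realizable on the lag axis.

        Raises :class:`ConfigurationError` if the window lies outside the
        realizable lag range or holds fewer than ``min_samples`` lag samples.
        """
        r_lo, r_hi = window
        if not 0 < r_lo < r_hi:
            raise ConfigurationError(f"fit window must satisfy 0 < r_lo < r_hi, got {window}")
        dr = self.lag_pixel
        if r_lo >= self.max_lag:
            raise ConfigurationError(
                f"fit window {window} um lies beyond the lag axis: "
                f"dr={dr:.4g} um, r_max={self.max_lag:.4g} um"
            )
        if (min(r_hi, self.max_lag) - r_lo) / dr < min_samples:
            raise ConfigurationError(
                f"fit window {window} um holds fewer than {min_samples} lag samples "
                f"(dr={dr:.4g} um, r_max={self.max_lag:.4g} um)"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)


def load_config_mapping(path: str | Path) -> dict:
    """Read a YAML or JSON mapping from disk."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return data


def dump_config_mapping(data: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
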