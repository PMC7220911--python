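"""Spectral-domain processing of raw a/LCI scans.

A raw acquisition records interferometric intensity as a function of
wavenumber and scattering angle theta_x at a single galvanometer position
theta_y. Fourier transforming along the spectral (wavenumber) dimension
resolves depth by coherence gating; stacking the transformed scans over the
galvanometer sweep assembles a depth-resolved stack of 2D angular scattering
planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawAlciScan",
    "ScatteringVolume",
    "NonUniformAxisError",
    "spectra_to_depth",
    "assemble_volume",
]


class NonUniformAxisError(ValueError):
    """Wavenumber axis is not evenly spaced; resample before transforming."""


@dataclass
class RawAlciScan:
    """One spectral-domain acquisition: intensity vs (wavenumber x theta_x).

    Attributes
    ----------
    intensity : ndarray, shape (n_k, n_theta_x)
        Nonnegative detected intensity.
    wavenumber : ndarray, shape (n_k,)
        Evenly spaced wavenumber axis (1/um), strictly monotonic.
    theta_x : ndarray, shape (n_theta_x,)
        Scattering-angle axis (radians), strictly monotonic.
    theta_y : float
        Galvanometer angle of this scan (radians).
    """

    intensity: np.ndarray
    wavenumber: np.ndarray
    theta_x: np.ndarray
    theta_y: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.theta_x = np.asarray(self.theta_x, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D (wavenumber x theta_x)")
        n_k, n_x = self.intensity.shape
        if self.wavenumber.shape != (n_k,) or self.theta_x.shape != (n_x,):
            raise ValueError("axis lengths do not match intensity shape")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensity must be finite and nonnegative")
        for name, ax in (("wavenumber", self.wavenumber), ("theta_x", self.theta_x)):
            d = np.diff(ax)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} axis must be strictly monotonic")


@dataclass
class ScatteringVolume:
    """Depth-resolved stack of 2D angular scattering planes.

    ``intensity`` is indexed (depth_pixel, theta_x, theta_y); the physical
    depth of pixel ``d`` is ``d * alci_pixel_to_depth`` micrometres.
    """

    intensity: np.ndarray
    theta_x: np.ndarray
    theta_y: np.ndarray
    alci_pixel_to_depth: float
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("volume intensity must be 3D (depth x theta_x x theta_y)")
        if np.any(self.intensity < 0) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("volume intensity must be finite and nonnegative")

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[0]

    def depth_axis(self) -> np.ndarray:
        """Physical depth (um) of each depth pixel."""
        return np.arange(self.n_depth) * self.alci_pixel_to_depth


def _check_uniform(axis: np.ndarray, rtol: float = 1e-6) -> None:
    d = np.diff(axis)
    step = np.mean(d)
    if step == 0 or np.max(np.abs(d - step)) > rtol * abs(step):
        raise NonUniformAxisError(
            "wavenumber axis is not evenly spaced (relative deviation exceeds "
            f"{rtol:g}); resample the spectrum onto a uniform axis first"
        )


def spectra_to_depth(
    scan: RawAlciScan,
    window: str = "hann",
    subtract_dc: bool = True,
    complex_output: bool = False,
) -> np.ndarray:
    """Transform one raw scan to a depth-resolved angular profile.

    Computes the one-sided discrete Fourier transform along the spectral
    dimension, per theta_x column, and returns its magnitude — a
    (n_depth x n_theta_x) array with ``n_depth = n_k // 2``.

    Parameters
    ----------
    window : {"hann", "none"}
        Spectral apodization applied before the transform.
    subtract_dc : bool
        Subtract the mean spectrum across theta_x before transforming. This
        suppresses the depth-independent reference/autocorrelation pedestal
        that otherwise dominates pixel 0; disable for single-column oracle
        checks.
    complex_output : bool
        Return the complex transform instead of its magnitude (the transform
        stage itself is linear; the magnitude is not).

    Notes
    -----
    Scaling: the transform is divided by ``sum(window)/2`` so a fringe of
    unit amplitude and integral cycle count maps to a unit-magnitude depth
    peak when ``window="none"``.
    """
    _check_uniform(scan.wavenumber)
    n_k = scan.intensity.shape[0]
    spec = scan.intensity.astype(float)
    if subtract_dc:
        spec = spec - spec.mean(axis=1, keepdims=True)
    if window == "hann":
        w = np.hanning(n_k)
    elif window in ("none", None):
        w = np.ones(n_k)
    else:
        raise ValueError(f"unknown apodization window {window!r}")
    f = np.fft.rfft(spec * w[:, None], axis=0)[: n_k // 2]
    f = f * (2.0 / w.sum())
    return f if complex_output else np.abs(f)


def assemble_volume(
    scans: list[RawAlciScan],
    window: str = "hann",
    subtract_dc: bool = True,
) -> ScatteringVolume:
    """Stack depth-transformed scans over the galvanometer (theta_y) sweep.

    Scans are sorted by their ``theta_y`` tag, so the result is independent
    of input order. All scans must share wavenumber and theta_x axes.
    """
    if not scans:
        raise ValueError("no scans given")
    order = np.argsort([s.theta_y for s in scans])
    scans = [scans[i] for i in order]
    ref = scans[0]
    for i, s in enumerate(scans[1:], start=1):
        if s.intensity.shape != ref.intensity.shape or not (
            np.allclose(s.wavenumber, ref.wavenumber) and np.allclose(s.theta_x, ref.theta_x)
        ):
            raise ValueError(f"scan {i} (theta_y={s.theta_y}) has mismatched axes")
    theta_y = np.array([s.theta_y for s in scans])
    if len(theta_y) > 1 and not np.all(np.diff(theta_y) > 0):
        raise ValueError("theta_y values must be distinct")
    planes = [spectra_to_depth(s, window=window, subtract_dc=subtract_dc) for s in scans]
    vol = np.stack(planes, axis=-1)  # (depth, theta_x, theta_y)
    # depth-pixel size follows from the wavenumber sampling: dz = pi / (n*dk)
    dk = float(np.mean(np.diff(ref.wavenumber)))
    dz = np.pi / (len(ref.wavenumber) * abs(dk))
    return ScatteringVolume(
        intensity=vol,
        theta_x=ref.theta_x.copy(),
        theta_y=theta_y,
        alci_pixel_to_depth=dz,
        provenance=tuple(f"theta_y={s.theta_y:.6g}" for s in scans),
    )
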