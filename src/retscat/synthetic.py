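"""Synthetic inputs for the whole pipeline, with full ground-truth bookkeeping.

Four generators cover everything the analysis consumes:

* 2D angular scattering planes whose azimuthally integrated two-point
  correlation follows a prescribed radial power law C(r) ~ r^(-alpha) between
  an inner and an outer length scale. Planes are synthesized in the
  correlation domain: the radial target (with per-pixel 1/r annulus
  compensation and seeded log-normal roughness) is inverse-transformed to the
  angular domain, and the plane is shifted to nonnegativity. The shift alters
  only the zero-lag pixel, which every slope fit excludes, so the analyzer's
  forward transform recovers the prescribed law exactly at all nonzero lags.
* Raw spectral-domain scans whose interferometric fringes encode reflector
  depths, so the spectral Fourier transform reproduces the depth profile.
* Layered OCT B-scans (NFL / OPL / RPE bright bands over a dim background)
  with multiplicative exponential speckle and exact boundary ground truth.
* Two-group (WT vs AD) cohorts of eyes x retinal locations with configurable
  group effects on the correlation slope, layer thickness and intensity
  level/variance, and compound-symmetric correlation of the per-eye metric
  deviations across locations.

Determinism: every generator is a pure function of its spec and seed; cohort
records derive per-record, per-stage child seeds from the master seed by a
fixed indexing scheme, so any record can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .config import LAYERS, QUADRANTS, ConfigurationError, OpticalConfig
from .layers import LayerBoundarySet, round_half_away
from .spectral import RawAlciScan, ScatteringVolume

__all__ = [
    "MediumSpec",
    "RetinaGeometry",
    "LayerGroupParams",
    "CohortSpec",
    "CohortRecord",
    "CohortDataset",
    "make_angular_plane",
    "make_raw_scan",
    "make_bscan",
    "inject_specular",
    "generate_cohort",
    "iter_cohort_records",
    "location_layout",
    "cs_noise",
]


# ---------------------------------------------------------------------------
# angular scattering planes with prescribed correlation power law


@dataclass(frozen=True)
class MediumSpec:
    """Target correlation structure of a synthetic scattering medium.

    ``alpha_true`` is the negative log-log slope of the azimuthally
    integrated correlation-energy curve between ``inner_scale`` and
    ``outer_scale`` (um); 0 <= alpha_true < 3 so the fractal dimension
    FD = 3 - alpha stays positive. ``noise_sigma`` is the log-normal
    roughness of the correlation target (seeded), giving realization-to-
    realization slope scatter.
    """

    alpha_true: float
    amplitude: float = 1.0
    inner_scale: float = 1.0
    outer_scale: float = 120.0
    seed: int = 0
    noise_sigma: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_true < 3.0:
            raise ValueError("alpha_true must lie in [0, 3)")
        if not 0 < self.inner_scale < self.outer_scale:
            raise ValueError("need 0 < inner_scale < outer_scale")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def _point_symmetrize(a: np.ndarray) -> np.ndarray:
    """Symmetrize under k -> -k (mod n) in FFT index space (both axes)."""
    rev0 = (-np.arange(a.shape[0])) % a.shape[0]
    rev1 = (-np.arange(a.shape[1])) % a.shape[1]
    return 0.5 * (a + a[np.ix_(rev0, rev1)])


def make_angular_plane(spec: MediumSpec, cfg: OpticalConfig) -> np.ndarray:
    """Synthesize a 2D angular scattering plane (theta_x x theta_y).

    The forward analysis (2D FFT magnitude, azimuthal annulus summation)
    applied to the returned plane yields a correlation-energy curve
    proportional to r^(-alpha_true) between the inner and outer scales, up
    to the seeded roughness. Because annulus pixel counts on a discrete lag
    lattice are lumpy at small radii, the per-pixel target is normalized by
    the exact count of its own annulus (bin width = one lag pixel), so the
    annulus *sums* follow the prescribed law by construction rather than
    only in the continuum limit.
    """
    cfg.validate_fit_window((max(spec.inner_scale, cfg.lag_pixel), spec.outer_scale),
                            min_samples=8)
    nx, ny = cfg.n_theta_x, cfg.n_theta_y
    dr = cfg.lag_pixel
    ix = np.fft.fftfreq(nx, d=1.0 / nx)  # signed lag indices
    iy = np.fft.fftfreq(ny, d=1.0 / ny)
    r = np.hypot(ix[:, None] * dr, iy[None, :] * dr)
    bin_idx = np.floor(r / dr).astype(int)
    counts = np.bincount(bin_idx.ravel())
    centers = (np.arange(len(counts)) + 0.5) * dr
    c_eff = np.clip(centers, spec.inner_scale, spec.outer_scale)
    per_bin = spec.amplitude * c_eff ** (-spec.alpha_true) / np.maximum(counts, 1)
    target = per_bin[bin_idx].astype(complex)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        eps = _point_symmetrize(rng.standard_normal((nx, ny)))
        target = target * np.exp(spec.noise_sigma * eps)
    # Random Hermitian phase: the angular field becomes a delocalized speckle
    # pattern (random scattered-field phases) while |FFT(plane)| is untouched.
    phi = rng.uniform(-np.pi, np.pi, (nx, ny))
    rev0 = (-np.arange(nx)) % nx
    rev1 = (-np.arange(ny)) % ny
    phi = 0.5 * (phi - phi[np.ix_(rev0, rev1)])
    target = target * np.exp(1j * phi)
    plane = np.fft.ifft2(target).real
    lo = plane.min()
    if lo < 0:
        plane = plane - lo
    return plane


def inject_specular(
    plane: np.ndarray, center: tuple[int, int], radius: int, gain: float
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply a disc of pixels by ``gain`` (a synthetic lens reflection).

    Returns the modified plane and the boolean footprint of the disc. The
    disc must lie entirely inside the plane.
    """
    plane = np.asarray(plane, dtype=float)
    cx, cy = center
    nx, ny = plane.shape
    if not (radius <= cx < nx - radius and radius <= cy < ny - radius):
        raise ValueError(f"disc center={center} radius={radius} not inside {plane.shape}")
    xx, yy = np.ogrid[:nx, :ny]
    footprint = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    out = plane.copy()
    out[footprint] *= gain
    return out, footprint


# ---------------------------------------------------------------------------
# raw spectral-domain scans


def make_raw_scan(
    depth_profile: list[tuple[float, float]],
    cfg: OpticalConfig,
    seed: int | None = None,
    noise_sigma: float = 0.0,
    theta_y: float = 0.0,
    angular_envelope: bool = True,
) -> RawAlciScan:
    """Synthesize one raw scan whose fringes encode the given reflectors.

    ``depth_profile`` lists (depth_um, reflectivity) pairs; each reflector
    contributes a cosine fringe of ``depth_um / alci_pixel_to_depth`` cycles
    across the spectral axis, so the spectral transform shows a peak at that
    depth pixel. With ``angular_envelope`` each reflector gets a smooth
    Gaussian theta_x falloff (oblique-illumination realism) so the
    depth-independent pedestal and the theta-varying signal are separable.
    Additive Gaussian read noise with standard deviation ``noise_sigma``.
    """
    n_k = cfg.n_wavenumber_samples
    n_x = cfg.n_theta_x
    k_idx = np.arange(n_k)
    total_refl = 0.0
    signal = np.zeros((n_k, n_x))
    x = np.arange(n_x)
    for depth_um, refl in depth_profile:
        if refl < 0:
            raise ValueError("reflectivity must be nonnegative")
        pixel = depth_um / cfg.alci_pixel_to_depth
        if not 0 <= depth_um <= cfg.max_depth:
            raise ValueError(
                f"depth {depth_um} um beyond the unambiguous range; maximum depth is "
                f"{cfg.max_depth:g} um for this wavenumber sampling"
            )
        if angular_envelope:
            env = np.exp(-((x - n_x / 2) ** 2) / (2 * (n_x / 4) ** 2))
        else:
            env = np.ones(n_x)
        fringe = np.cos(2 * np.pi * pixel * k_idx / n_k)
        signal += refl * fringe[:, None] * env[None, :]
        total_refl += refl
    intensity = 1.0 + total_refl + signal  # reference pedestal keeps it nonnegative
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0, noise_sigma, intensity.shape), 0, None)
    dk = np.pi / (n_k * cfg.alci_pixel_to_depth)
    k_center = 2 * np.pi / cfg.center_wavelength
    wavenumber = k_center + (k_idx - n_k / 2) * dk
    theta_x = (x - n_x / 2) * cfg.theta_span / n_x
    return RawAlciScan(intensity=intensity, wavenumber=wavenumber, theta_x=theta_x,
                       theta_y=theta_y)


# ---------------------------------------------------------------------------
# layered OCT B-scans


@dataclass(frozen=True)
class RetinaGeometry:
    """Axial layout (um) of the synthetic retina and B-scan rendering levels."""

    vitreous_um: float = 30.0
    inner_gap_um: float = 40.0  # IPL + INL between NFL and OPL
    outer_gap_um: float = 50.0  # ONL between OPL and RPE
    below_um: float = 30.0
    n_cols: int = 128
    background: float = 0.02
    inner_gap_level: float = 0.15
    outer_gap_level: float = 0.10


DEFAULT_CONTRASTS = {"NFL": 1.0, "OPL": 0.85, "RPE": 0.95}


def make_bscan(
    layer_thicknesses_um: dict[str, float],
    cfg: OpticalConfig,
    contrasts: dict[str, float] | None = None,
    speckle_level: float = 0.0,
    seed: int | None = None,
    geometry: RetinaGeometry | None = None,
) -> tuple[np.ndarray, LayerBoundarySet]:
    """Render a layered B-scan plus its exact boundary ground truth.

    The noiseless template is piecewise constant in depth; each layer spans
    ``round(thickness / oct_axial_pixel)`` rows (at least one). Speckle is
    multiplicative with unit mean: ``img = template * ((1 - s) + s * Exp(1))``
    for ``s = speckle_level`` in [0, 1].
    """
    geometry = geometry or RetinaGeometry()
    contrasts = {**DEFAULT_CONTRASTS, **(contrasts or {})}
    if not 0.0 <= speckle_level <= 1.0:
        raise ValueError("speckle_level must lie in [0, 1]")
    ax = cfg.oct_axial_pixel
    missing = [l for l in LAYERS if l not in layer_thicknesses_um]
    if missing:
        raise ValueError(f"missing layer thicknesses: {missing}")
    if any(layer_thicknesses_um[l] <= 0 for l in LAYERS):
        raise ValueError("layer thicknesses must be positive")

    gaps_after = {"NFL": (geometry.inner_gap_um, geometry.inner_gap_level),
                  "OPL": (geometry.outer_gap_um, geometry.outer_gap_level),
                  "RPE": (geometry.below_um, geometry.background)}
    boundaries: dict[str, tuple[int, int]] = {}
    segments: list[tuple[int, float]] = [(max(round_half_away(geometry.vitreous_um / ax), 1),
                                          geometry.background)]
    for layer in LAYERS:
        rows = max(round_half_away(layer_thicknesses_um[layer] / ax), 1)
        top = sum(s[0] for s in segments)
        boundaries[layer] = (top, top + rows)
        segments.append((rows, contrasts[layer]))
        gap_um, gap_level = gaps_after[layer]
        segments.append((max(round_half_away(gap_um / ax), 1), gap_level))
    n_rows = sum(s[0] for s in segments)
    template = np.empty((n_rows, geometry.n_cols))
    row = 0
    for rows, level in segments:
        template[row : row + rows] = level
        row += rows
    if speckle_level > 0:
        rng = np.random.default_rng(seed)
        img = template * ((1.0 - speckle_level)
                          + speckle_level * rng.exponential(1.0, template.shape))
    else:
        img = template.copy()
    truth = LayerBoundarySet(boundaries=boundaries, oct_axial_pixel=ax)
    return img, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class LayerGroupParams:
    """Per-layer, per-group generative parameters.

    ``alpha`` is the correlation-slope target, ``intensity`` the pixel-mean
    level of the layer's angular plane (arbitrary units), ``var`` its pixel
    variance, and ``thickness`` the layer thickness in micrometres; each has
    a between-record standard deviation.
    """

    alpha_mean: float
    alpha_sd: float
    intensity_mean: float
    intensity_sd: float
    var_mean: float
    var_sd: float
    thickness_mean_um: float
    thickness_sd_um: float


def _wt_defaults() -> dict[str, LayerGroupParams]:
    return {
        "NFL": LayerGroupParams(0.8, 0.12, 5.0, 0.5, 1.0, 0.15, 18.0, 1.2),
        "OPL": LayerGroupParams(0.8, 0.12, 4.0, 0.4, 0.8, 0.12, 15.0, 1.2),
        "RPE": LayerGroupParams(0.9, 0.12, 4.5, 0.45, 0.9, 0.13, 15.0, 1.2),
    }


def _ad_defaults() -> dict[str, LayerGroupParams]:
    # Effects in the directions the analysis is designed to detect:
    # thinner NFL, higher alpha in all layers, higher NFL intensity level
    # (superior quadrant only, via ad_intensity_mean_quadrants) and variance.
    wt = _wt_defaults()
    return {
        "NFL": replace(wt["NFL"], alpha_mean=1.0, intensity_mean=6.5, var_mean=1.4,
                       thickness_mean_um=16.0),
        "OPL": replace(wt["OPL"], alpha_mean=1.0),
        "RPE": replace(wt["RPE"], alpha_mean=1.1),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Design of a two-group (WT vs AD) synthetic cohort.

    Defaults follow the study design this pipeline targets: 10 WT and 13 AD
    eyes, 8 retinal locations per eye at 500 um offsets around the optic
    nerve head, and compound-symmetric within-eye correlation of the metric
    deviations (small and negative by default; the admissible range for k
    locations is -1/(k-1) < rho < 1).

    ``ad_intensity_mean_quadrants`` restricts the AD-vs-WT intensity *level*
    difference to the named quadrants (None applies it everywhere); the
    variance difference is always quadrant-uniform.
    """

    n_wt_eyes: int = 10
    n_ad_eyes: int = 13
    n_locations: int = 8
    layer_params: dict[str, dict[str, LayerGroupParams]] = field(
        default_factory=lambda: {"WT": _wt_defaults(), "AD": _ad_defaults()}
    )
    within_eye_rho: float = -0.14
    seed: int = 0
    speckle_level: float = 0.3
    ad_intensity_mean_quadrants: tuple[str, ...] | None = ("superior",)
    specular_prob: float = 0.0
    specular_gain: float = 8.0
    specular_radius: int = 3
    medium_noise_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.n_wt_eyes < 2 or self.n_ad_eyes < 2 or self.n_locations < 2:
            raise ValueError("need >= 2 eyes per group and >= 2 locations")
        lo = -1.0 / (self.n_locations - 1)
        if not lo < self.within_eye_rho < 1.0:
            raise ValueError(
                f"within_eye_rho must lie in ({lo:.6g}, 1) for "
                f"{self.n_locations} locations, got {self.within_eye_rho}"
            )
        for g in ("WT", "AD"):
            if g not in self.layer_params:
                raise ValueError(f"layer_params missing group {g!r}")
            for l in LAYERS:
                if l not in self.layer_params[g]:
                    raise ValueError(f"layer_params[{g!r}] missing layer {l!r}")
        if self.ad_intensity_mean_quadrants is not None:
            unknown = set(self.ad_intensity_mean_quadrants) - set(QUADRANTS)
            if unknown:
                raise ValueError(f"unknown quadrants: {sorted(unknown)}")

    @classmethod
    def null_design(cls, **overrides) -> "CohortSpec":
        """Both groups share the WT parameters — no effects anywhere."""
        params = {"WT": _wt_defaults(), "AD": _wt_defaults()}
        overrides.setdefault("ad_intensity_mean_quadrants", None)
        return cls(layer_params=params, **overrides)


def location_layout(n_locations: int) -> list[tuple[tuple[float, float], str]]:
    """Offsets (um) and quadrant tags of the sampled retinal locations.

    Locations sit at multiples of 500 um along the horizontal and vertical
    axes through the optic nerve head, cycling +X, -X, +Y, -Y with growing
    radius; +Y is superior, -Y inferior, +X nasal, -X temporal. For the
    8-location design this is the two nearest rings on each half-axis.
    """
    dirs = [((1, 0), "nasal"), ((-1, 0), "temporal"), ((0, 1), "superior"), ((0, -1), "inferior")]
    out = []
    for i in range(n_locations):
        (dx, dy), quad = dirs[i % 4]
        mag = 500.0 * (i // 4 + 1)
        out.append(((dx * mag, dy * mag), quad))
    return out


def cs_noise(k: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance k-vector with compound-symmetric correlation rho."""
    z = rng.standard_normal(k)
    zbar = z.mean()
    lam_mean = 1.0 + (k - 1) * rho  # eigenvalue of the mean direction
    return np.sqrt(1.0 - rho) * (z - zbar) + np.sqrt(max(lam_mean, 0.0)) * zbar


@dataclass
class CohortRecord:
    """One (eye, location) acquisition with its ground truth."""

    eye: str
    group: str
    location: int
    quadrant: str
    offset_um: tuple[float, float]
    truth: dict[str, dict[str, float]]  # layer -> parameter truth
    bscan: np.ndarray | None = None
    truth_bounds: LayerBoundarySet | None = None
    volume: ScatteringVolume | None = None
    planes: dict[str, np.ndarray] | None = None
    artifacts: dict[str, np.ndarray] | None = None  # layer -> footprint


@dataclass
class CohortDataset:
    spec: CohortSpec
    cfg: OpticalConfig
    records: list[CohortRecord]
    truth: pd.DataFrame

    def truth_table(self) -> pd.DataFrame:
        """Ground-truth metric values in long cohort-table format."""
        metric_map = {
            "alpha_true": "alpha",
            "intensity_mean_true": "intensity_mean",
            "intensity_var_true": "intensity_variance",
            "thickness_um_true": "thickness_um",
        }
        keys = ["eye", "group", "location", "quadrant", "layer"]
        long = self.truth.melt(id_vars=keys, value_vars=list(metric_map),
                               var_name="metric", value_name="value")
        long["metric"] = long["metric"].map(metric_map)
        return long


def _draw_eye_params(
    spec: CohortSpec, group: str, quadrants: list[str], rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    """Per-layer location vectors of (alpha, intensity mean, variance, thickness)."""
    k = spec.n_locations
    out: dict[str, dict[str, np.ndarray]] = {}
    for layer in LAYERS:
        p = spec.layer_params[group][layer]
        p_wt = spec.layer_params["WT"][layer]
        mean_int = np.full(k, p.intensity_mean)
        if (group == "AD" and spec.ad_intensity_mean_quadrants is not None):
            allowed = set(spec.ad_intensity_mean_quadrants)
            off = np.array([q not in allowed for q in quadrants])
            mean_int[off] = p_wt.intensity_mean
        out[layer] = {
            "alpha": np.clip(p.alpha_mean + p.alpha_sd * cs_noise(k, spec.within_eye_rho, rng),
                             0.05, 2.95),
            "intensity_mean": np.clip(
                mean_int + p.intensity_sd * cs_noise(k, spec.within_eye_rho, rng), 0.2, None),
            "intensity_var": np.clip(
                p.var_mean + p.var_sd * cs_noise(k, spec.within_eye_rho, rng), 1e-3, None),
            "thickness_um": np.clip(
                p.thickness_mean_um
                + p.thickness_sd_um * cs_noise(k, spec.within_eye_rho, rng), 4.0, None),
        }
    return out


def _alci_interval(top_row: int, bottom_row: int, cfg: OpticalConfig,
                   n_depth: int) -> tuple[int, int]:
    ratio = cfg.oct_axial_pixel / cfg.alci_pixel_to_depth
    t = int(round_half_away(top_row * ratio))
    b = int(round_half_away(bottom_row * ratio))
    if b <= t:
        b = t + 1
    b = min(b, n_depth)
    t = min(t, b - 1)
    return t, b


def iter_cohort_records(
    spec: CohortSpec, cfg: OpticalConfig, mode: str = "volumes"
) -> Iterator[CohortRecord]:
    """Generate cohort records one at a time (memory-friendly).

    ``mode`` selects the payload: "table" (ground truth only), "planes"
    (per-layer angular planes + B-scan), or "volumes" (scattering volume +
    B-scan, the full registration path).
    """
    if mode not in ("table", "planes", "volumes"):
        raise ValueError(f"unknown mode {mode!r}")
    layout = location_layout(spec.n_locations)
    quadrants = [q for _, q in layout]
    eyes = [("WT", i) for i in range(spec.n_wt_eyes)] + [
        ("AD", i) for i in range(spec.n_ad_eyes)
    ]
    background = 0.05
    for eye_idx, (group, gi) in enumerate(eyes):
        eye_id = f"{group}{gi:02d}"
        rng_eye = np.random.default_rng(np.random.SeedSequence([spec.seed, eye_idx, 0]))
        params = _draw_eye_params(spec, group, quadrants, rng_eye)
        for loc in range(spec.n_locations):
            offset, quadrant = layout[loc]
            truth = {
                layer: {
                    "alpha_true": float(params[layer]["alpha"][loc]),
                    "intensity_mean_true": float(params[layer]["intensity_mean"][loc]),
                    "intensity_var_true": float(params[layer]["intensity_var"][loc]),
                    "thickness_um_true": float(params[layer]["thickness_um"][loc]),
                }
                for layer in LAYERS
            }
            rec = CohortRecord(eye=eye_id, group=group, location=loc,
                               quadrant=quadrant, offset_um=offset, truth=truth)
            if mode == "table":
                yield rec
                continue
            thicknesses = {l: truth[l]["thickness_um_true"] for l in LAYERS}
            bscan_seed = np.random.SeedSequence([spec.seed, eye_idx, loc, 2])
            rec.bscan, rec.truth_bounds = make_bscan(
                thicknesses, cfg, speckle_level=spec.speckle_level,
                seed=bscan_seed.generate_state(1)[0],
            )
            planes: dict[str, np.ndarray] = {}
            artifacts: dict[str, np.ndarray] = {}
            rng_loc = np.random.default_rng(np.random.SeedSequence([spec.seed, eye_idx, loc, 3]))
            for li, layer in enumerate(LAYERS):
                mspec = MediumSpec(
                    alpha_true=truth[layer]["alpha_true"],
                    noise_sigma=spec.medium_noise_sigma,
                    seed=int(np.random.SeedSequence(
                        [spec.seed, eye_idx, loc, 1, li]).generate_state(1)[0]),
                )
                raw = make_angular_plane(mspec, cfg)
                sd = raw.std()
                u = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
                m = truth[layer]["intensity_mean_true"]
                s = np.sqrt(truth[layer]["intensity_var_true"])
                plane = np.clip(m + s * u, 0.0, None)
                if spec.specular_prob > 0 and rng_loc.random() < spec.specular_prob:
                    r = spec.specular_radius
                    cx = int(rng_loc.integers(r, cfg.n_theta_x - r))
                    cy = int(rng_loc.integers(r, cfg.n_theta_y - r))
                    plane, footprint = inject_specular(plane, (cx, cy), r, spec.specular_gain)
                    artifacts[layer] = footprint
                planes[layer] = plane
            rec.artifacts = artifacts or None
            if mode == "planes":
                rec.planes = planes
            else:
                n_depth = cfg.n_depth
                vol = np.full((n_depth, cfg.n_theta_x, cfg.n_theta_y), background)
                for layer in LAYERS:
                    top_row, bottom_row = rec.truth_bounds.boundaries[layer]
                    t, b = _alci_interval(top_row, bottom_row, cfg, n_depth)
                    vol[t:b] = planes[layer]
                rec.volume = ScatteringVolume(
                    intensity=vol,
                    theta_x=(np.arange(cfg.n_theta_x) - cfg.n_theta_x / 2)
                    * cfg.theta_span / cfg.n_theta_x,
                    theta_y=(np.arange(cfg.n_theta_y) - cfg.n_theta_y / 2)
                    * cfg.theta_span / cfg.n_theta_y,
                    alci_pixel_to_depth=cfg.alci_pixel_to_depth,
                    provenance=(eye_id, str(loc)),
                )
            yield rec


def generate_cohort(
    spec: CohortSpec, cfg: OpticalConfig, mode: str = "volumes"
) -> CohortDataset:
    """Materialize a full cohort dataset with its ground-truth table.

    The record count is (n_wt_eyes + n_ad_eyes) * n_locations, each record
    carrying exactly one ground-truth entry per layer. For large designs in
    "volumes" mode prefer :func:`iter_cohort_records`.
    """
    records = list(iter_cohort_records(spec, cfg, mode=mode))
    rows = []
    for rec in records:
        for layer in LAYERS:
            row = dict(eye=rec.eye, group=rec.group, location=rec.location,
                       quadrant=rec.quadrant, layer=layer, **rec.truth[layer])
            if rec.truth_bounds is not None:
                top, bottom = rec.truth_bounds.boundaries[layer]
                row["top_row_true"] = top
                row["bottom_row_true"] = bottom
            row["has_artifact"] = bool(rec.artifacts and layer in rec.artifacts)
            rows.append(row)
    return CohortDataset(spec=spec, cfg=cfg, records=records, truth=pd.DataFrame(rows))
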