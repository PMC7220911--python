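"""OCT layer segmentation and registration into a/LCI depth coordinates.

The three analyzed retinal layers — nerve fiber layer (NFL), outer plexiform
layer (OPL) and retinal pigmented epithelium (RPE) — appear as bright bands
in an OCT B-scan. Their boundaries are found per column from axial gradient
peaks, reduced to a single boundary set per B-scan by a column median, and
mapped into a/LCI depth pixels by the ratio of the two axial pixel sizes.
Per-layer 2D angular planes are then extracted from a scattering volume by
averaging over the mapped depth interval.

Pixel conventions, used everywhere: 0-based indices, half-open intervals
[top, bottom), and round-half-away-from-zero when converting between pixel
grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import LAYERS
from .spectral import ScatteringVolume

__all__ = [
    "LayerBoundarySet",
    "AngularPlaneWithMask",
    "SegmentationError",
    "segment_layers",
    "layer_thickness",
    "map_to_alci",
    "extract_layer_plane",
    "detect_specular",
    "apply_specular_mask",
    "round_half_away",
]


class SegmentationError(RuntimeError):
    """B-scan could not be segmented (insufficient contrast / missing bands)."""


def round_half_away(x):
    """Round half away from zero (0.5 -> 1, -0.5 -> -1); returns int array/scalar."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out.astype(int) if out.ndim else int(out)


@dataclass
class LayerBoundarySet:
    """Named layer boundaries in OCT rows, optionally mapped to a/LCI pixels.

    ``boundaries`` maps layer name -> (top_px, bottom_px), half-open
    [top, bottom) row intervals ordered NFL above OPL above RPE.
    """

    boundaries: dict[str, tuple[int, int]]
    oct_axial_pixel: float
    alci_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    alci_pixel_to_depth: float | None = None

    def __post_init__(self) -> None:
        prev_bottom = -1
        for layer in [l for l in LAYERS if l in self.boundaries]:
            top, bottom = self.boundaries[layer]
            if not 0 <= top < bottom:
                raise ValueError(f"{layer}: invalid interval [{top}, {bottom})")
            if top < prev_bottom:
                raise ValueError(f"{layer} overlaps the layer above it")
            prev_bottom = bottom
        if self.oct_axial_pixel <= 0:
            raise ValueError("oct_axial_pixel must be positive")

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(l for l in LAYERS if l in self.boundaries)


@dataclass
class AngularPlaneWithMask:
    """A per-layer 2D angular scattering plane plus its exclusion mask.

    ``mask`` is True where pixels are excluded (specular artifacts, user
    masks). Records retaining less than half their pixels are flagged rather
    than silently analyzed.
    """

    intensity: np.ndarray
    mask: np.ndarray
    layer: str = ""
    eye: str = ""
    group: str = ""
    location: int = -1
    quadrant: str = ""
    flagged: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.intensity.shape:
            raise ValueError("mask shape must match intensity shape")
        if self.mask.mean() > 0.5:
            self.flagged = True

    @property
    def retained(self) -> np.ndarray:
        """1D array of non-excluded pixel values."""
        return self.intensity[~self.mask]


# ---------------------------------------------------------------------------
# segmentation


def _column_bands(profile: np.ndarray, smoothed: np.ndarray, n_layers: int,
                  prominence: float, search: int):
    """Locate ``n_layers`` bright bands in one column; return (top, bottom) rows."""
    from scipy.signal import find_peaks

    peaks, props = find_peaks(smoothed, prominence=prominence)
    if len(peaks) < n_layers:
        return None
    keep = np.argsort(props["prominences"])[-n_layers:]
    peaks = np.sort(peaks[keep])
    grad = np.diff(profile)
    bands = []
    for p in peaks:
        lo = max(p - search, 0)
        hi = min(p + search, len(grad))
        if p <= lo or p >= hi:
            return None
        top = lo + int(np.argmax(grad[lo:p])) + 1
        bottom = p + int(np.argmin(grad[p:hi])) + 1
        if bottom <= top:
            return None
        bands.append((top, bottom))
    # bands must not overlap
    for (t0, b0), (t1, b1) in zip(bands, bands[1:]):
        if t1 < b0:
            return None
    return bands


def segment_layers(
    bscan: np.ndarray,
    n_layers: int = 3,
    oct_axial_pixel: float = 2.0,
    lateral_median: int = 11,
    prominence_frac: float = 0.25,
    search_px: int = 12,
    min_valid_frac: float = 0.5,
) -> LayerBoundarySet:
    """Segment the bright retinal bands of a B-scan into layer boundaries.

    Speckle is suppressed with a lateral (within-row) median filter that
    leaves axial edges untouched; per column, band candidates come from
    prominence-filtered peaks of a lightly smoothed axial profile, and band
    edges from the extrema of the raw axial gradient near each peak. The
    per-column boundaries are reduced to one set per B-scan by a column
    median.

    Raises
    ------
    SegmentationError
        If fewer than ``n_layers`` bands are resolvable in a majority of
        columns — the caller may drop the record, as real studies drop
        B-scans with insufficient contrast.
    """
    img = np.asarray(bscan, dtype=float)
    if img.ndim != 2:
        raise ValueError("bscan must be a 2D image (depth x lateral)")
    if not np.any(img > 0):
        raise SegmentationError("B-scan has no signal")
    if lateral_median > 1:
        img = ndimage.median_filter(img, size=(1, lateral_median), mode="nearest")
    smooth = ndimage.uniform_filter1d(img, size=3, axis=0, mode="nearest")
    scale = float(np.max(smooth) - np.median(smooth))
    if scale <= 0:
        raise SegmentationError("B-scan has no axial contrast")
    prominence = prominence_frac * scale

    n_cols = img.shape[1]
    tops = np.full((n_layers, n_cols), np.nan)
    bottoms = np.full((n_layers, n_cols), np.nan)
    n_valid = 0
    for j in range(n_cols):
        bands = _column_bands(img[:, j], smooth[:, j], n_layers, prominence, search_px)
        if bands is None:
            continue
        n_valid += 1
        for i, (t, b) in enumerate(bands):
            tops[i, j] = t
            bottoms[i, j] = b
    if n_valid < min_valid_frac * n_cols:
        raise SegmentationError(
            f"only {n_valid}/{n_cols} columns yielded {n_layers} resolvable bands"
        )
    boundaries = {}
    for i, layer in enumerate(LAYERS[:n_layers]):
        top = int(round_half_away(np.nanmedian(tops[i])))
        bottom = int(round_half_away(np.nanmedian(bottoms[i])))
        if bottom <= top:
            bottom = top + 1
        boundaries[layer] = (top, bottom)
    return LayerBoundarySet(boundaries=boundaries, oct_axial_pixel=oct_axial_pixel)


def layer_thickness(bounds: LayerBoundarySet, layer: str) -> float:
    """Physical thickness (um) of a segmented layer: (bottom - top) * pixel size."""
    if layer not in bounds.boundaries:
        raise KeyError(f"unknown layer {layer!r}; have {sorted(bounds.boundaries)}")
    top, bottom = bounds.boundaries[layer]
    return (bottom - top) * bounds.oct_axial_pixel


def map_to_alci(
    bounds: LayerBoundarySet,
    alci_pixel_to_depth: float,
    volume_depth: int | None = None,
) -> LayerBoundarySet:
    """Map OCT row boundaries to a/LCI depth-pixel intervals.

    Each row index is scaled by ``oct_axial_pixel / alci_pixel_to_depth`` and
    rounded half away from zero; intervals stay half-open, are widened to a
    minimum of one pixel, and are clamped (with a warning) to the volume
    depth when it is given.
    """
    if alci_pixel_to_depth <= 0:
        raise ValueError("alci_pixel_to_depth must be positive")
    ratio = bounds.oct_axial_pixel / alci_pixel_to_depth
    intervals = {}
    for layer, (top, bottom) in bounds.boundaries.items():
        a_top = int(round_half_away(top * ratio))
        a_bot = int(round_half_away(bottom * ratio))
        if a_bot <= a_top:
            a_bot = a_top + 1
        if volume_depth is not None and a_bot > volume_depth:
            warnings.warn(
                f"{layer}: mapped interval [{a_top}, {a_bot}) exceeds volume depth "
                f"{volume_depth}; clamping", stacklevel=2,
            )
            a_bot = volume_depth
            a_top = min(a_top, a_bot - 1)
        intervals[layer] = (a_top, a_bot)
    return LayerBoundarySet(
        boundaries=dict(bounds.boundaries),
        oct_axial_pixel=bounds.oct_axial_pixel,
        alci_intervals=intervals,
        alci_pixel_to_depth=alci_pixel_to_depth,
    )


def extract_layer_plane(
    volume: ScatteringVolume,
    bounds: LayerBoundarySet,
    layer: str,
    agg: str = "mean",
    **meta,
) -> AngularPlaneWithMask:
    """Average the scattering volume over a layer's mapped depth interval.

    Returns the per-(theta_x, theta_y) mean (or sum with ``agg="sum"``) of
    the volume over the layer's a/LCI depth pixels, with an empty exclusion
    mask.
    """
    if layer not in bounds.alci_intervals:
        raise KeyError(f"layer {layer!r} has no mapped a/LCI interval; call map_to_alci")
    top, bottom = bounds.alci_intervals[layer]
    if top < 0 or bottom > volume.n_depth:
        raise ValueError(
            f"{layer}: interval [{top}, {bottom}) outside volume depth {volume.n_depth}"
        )
    block = volume.intensity[top:bottom]
    plane = block.sum(axis=0) if agg == "sum" else block.mean(axis=0)
    return AngularPlaneWithMask(
        intensity=plane, mask=np.zeros(plane.shape, dtype=bool), layer=layer, **meta
    )


# ---------------------------------------------------------------------------
# specular artifact masking


def detect_specular(
    plane: np.ndarray,
    user_mask: np.ndarray | None = None,
    saturation_factor: float = 5.0,
    dilate_px: int = 2,
    min_area: int = 4,
) -> np.ndarray:
    """Detect specular hot spots in an angular plane; return an exclusion mask.

    A specular (lens) reflection saturates far above the tissue-scattering
    level, so the rule is multiplicative: pixels brighter than
    ``saturation_factor`` times the plane median are candidates. A
    dispersion-based (sigma/MAD) threshold is deliberately not used — it
    would trim legitimate speckle-tail pixels, and because the tail mass
    depends on the medium's correlation structure, that trimming would bias
    intensity statistics differently across groups. Candidates are grouped
    into connected components; components smaller than ``min_area`` pixels
    are ignored (a reflection is a compact spot, isolated bright pixels are
    speckle). Surviving components are dilated by ``dilate_px``. A
    user-supplied mask overrides the automatic rule entirely (the analogue
    of manual segmentation of the lens reflection).
    """
    plane = np.asarray(plane, dtype=float)
    if np.any(plane < 0):
        raise ValueError("plane must be nonnegative")
    if user_mask is not None:
        user_mask = np.asarray(user_mask, dtype=bool)
        if user_mask.shape != plane.shape:
            raise ValueError("user mask shape must match plane shape")
        return user_mask.copy()
    med = float(np.median(plane))
    scale = med if med > 0 else float(plane.mean())
    if scale <= 0:  # all-zero plane: nothing can saturate
        return np.zeros(plane.shape, dtype=bool)
    hot = plane > saturation_factor * scale
    if not hot.any():
        return np.zeros(plane.shape, dtype=bool)
    labels, n_comp = ndimage.label(hot)
    if min_area > 1 and n_comp:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        hot[np.isin(labels, small[small > 0])] = False
    mask = hot
    if dilate_px > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate_px)
    return mask


def apply_specular_mask(
    plane: AngularPlaneWithMask, user_mask: np.ndarray | None = None, **kwargs
) -> AngularPlaneWithMask:
    """Attach a detected (or user-supplied) specular mask to a plane record."""
    mask = detect_specular(plane.intensity, user_mask=user_mask, **kwargs)
    return AngularPlaneWithMask(
        intensity=plane.intensity,
        mask=plane.mask | mask,
        layer=plane.layer,
        eye=plane.eye,
        group=plane.group,
        location=plane.location,
        quadrant=plane.quadrant,
    )
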