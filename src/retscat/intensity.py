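"""Histogram statistics of per-layer angular scattering intensity.

For each isolated (masked) 2D scattering distribution the retained pixels
define an intensity histogram with pixel counts k per bin and N total
pixels; the moments reported — mean, population variance (divisor N),
skewness and excess kurtosis — are computed directly from the retained
pixels, which is exactly the k/N histogram formula with singleton bins and
avoids binning bias. The histogram itself is kept for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layers import AngularPlaneWithMask

__all__ = [
    "IntensityHistogram",
    "IntensityStats",
    "InsufficientPixelsError",
    "histogram_stats",
    "normalize_group",
]


class InsufficientPixelsError(ValueError):
    """Too few retained pixels for meaningful intensity statistics."""


@dataclass
class IntensityHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int
    layer: str = ""
    eye: str = ""
    location: int = -1

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("histogram counts must sum to N")
        if self.n_total <= 0:
            raise ValueError("N must be positive")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")


@dataclass(frozen=True)
class IntensityStats:
    """Moments of the retained-pixel intensity distribution (population N)."""

    mean: float
    variance: float
    skewness: float
    kurtosis: float  # excess kurtosis (0 for a normal distribution)
    n: int

    def summary(self) -> str:
        return (
            f"N={self.n}: mean={self.mean:.5g}, var={self.variance:.5g}, "
            f"skew={self.skewness:.4g}, exkurt={self.kurtosis:.4g}"
        )


def histogram_stats(
    plane: AngularPlaneWithMask,
    n_bins: int = 64,
    min_pixels: int = 100,
) -> tuple[IntensityHistogram, IntensityStats]:
    """Masked histogram and intensity moments of one angular plane.

    Raises :class:`InsufficientPixelsError` when fewer than ``min_pixels``
    pixels survive the exclusion mask; callers treat this as a flagged
    (droppable) record.
    """
    x = plane.retained
    n = x.size
    if n < min_pixels:
        raise InsufficientPixelsError(
            f"only {n} retained pixels (< {min_pixels}); record flagged"
        )
    mean = float(x.sum() / n)
    d = x - mean
    m2 = float(np.sum(d**2) / n)
    if m2 > 0:
        m3 = float(np.sum(d**3) / n)
        m4 = float(np.sum(d**4) / n)
        skew = m3 / m2**1.5
        exkurt = m4 / m2**2 - 3.0
    else:  # constant plane: shape moments are conventionally zero
        skew = 0.0
        exkurt = 0.0
    counts, edges = np.histogram(x, bins=n_bins)
    hist = IntensityHistogram(
        bin_edges=edges, counts=counts, n_total=n,
        layer=plane.layer, eye=plane.eye, location=plane.location,
    )
    stats = IntensityStats(mean=mean, variance=m2, skewness=skew, kurtosis=exkurt, n=n)
    return hist, stats


def normalize_group(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    reference_group: str = "WT",
    by: tuple[str, ...] = ("metric", "layer"),
) -> pd.DataFrame:
    """Divide each value by the reference-group mean of its (metric, layer).

    Display-only normalization: the reference (WT) group's normalized mean is
    1 by construction, and scaling does not alter any downstream test
    statistic computed on the same records.
    """
    out = table.copy()
    by = [c for c in by if c in out.columns]
    ref = out[out[group_col] == reference_group]
    if ref.empty:
        raise ValueError(f"no rows for reference group {reference_group!r}")
    ref_means = ref.groupby(by)[value_col].mean() if by else ref[value_col].mean()
    if by:
        denom = out.set_index(by).index.map(ref_means)
        denom = np.asarray(denom, dtype=float)
    else:
        denom = np.full(len(out), float(ref_means))
    if np.any(~np.isfinite(denom)) or np.any(denom == 0):
        raise ValueError("reference-group mean is zero or undefined for some stratum")
    out[value_col] = out[value_col].to_numpy(dtype=float) / denom
    return out
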