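# Methods

This note documents the model, coordinate conventions, numerical choices and
default parameters of `retscat`. It is self-contained: every stated size,
window and rate is a package choice, defined here.

## 1. Physical model and coordinate convention

An angle-resolved low-coherence interferometry (a/LCI) acquisition records,
for each depth in the sample, a 2D angular distribution of scattered light
I(θx, θy). The Fourier transform of the angular distribution is the two-point
spatial correlation of the optical field: structure at transverse separation
r in the sample appears as intensity modulation at angle θ ≈ r·(2π/λ)⁻¹, so
the discrete 2D FFT of an angular plane yields the correlation over a grid of
spatial lags.

One convention links the two domains everywhere in the package:

- scattering vector: `q = (2π/λ)·θ` (small-angle approximation),
- lag pixel: `δr = λ / Θ` where Θ is the full angular span covered by the
  detector (`theta_span`),
- maximum on-axis lag: `r_max = (n/2)·δr` for an n-pixel angular axis.

With the defaults (λ = 0.830 µm, Θ = 0.830 rad, n = 128) this gives
δr = 1.0 µm and r_max = 64 µm, so the short-range fit window below is well
inside the sampled lag range. `OpticalConfig.validate_fit_window` rejects any
window/geometry combination that would leave fewer than a minimum number of
lag bins, naming δr and r_max in the error.

Depth processing follows standard spectral-domain interferometry: each θx
column of a raw spectrum (intensity vs wavenumber k, uniform grid required —
non-uniform axes raise an error instructing resampling) is apodized (Hann by
default), DC-suppressed (subtraction of the mean spectrum across θx), and
one-sided FFT'd. Depth pixel m holds the magnitude of the m-cycles-per-sweep
fringe; the depth pixel size is `dz = π / (n_k · δk)`. A separate calibration
scalar (`alci_pixel_to_depth`, default 10 µm/pixel) links spectrometer depth
pixels to physical depth in tissue and is the quantity used to co-register
OCT boundaries into the a/LCI volume.

## 2. Correlation-energy curve and power-law slope

For one angular plane (optionally with an exclusion mask; excluded pixels are
filled with the retained-pixel median to avoid spectral leakage from a hard
hole):

1. `angular_to_correlation` — magnitude of the centered 2D FFT, lag axes in
   µm per the convention above.
2. `azimuthal_integrate` — annulus *sums* (integration, not averaging) of the
   correlation magnitude over radial lag bins of width δr. The zero-lag pixel
   (total power, not texture) is excluded.
3. `fit_slope` — ordinary least squares of log10(energy) on log10(lag)
   restricted to the fit window; `alpha` is the negative slope. The default
   short-range window is 2–10 µm (cellular / sub-cellular texture); an
   optional long-range window (default 20–100 µm) probes larger-scale
   organization and requires a geometry whose r_max covers it.

The fractal dimension is the derived identity `FD = 3 − α`, implemented as a
property of the fit object so it can never drift from the fitted slope.

Statistical inference is performed on α (and FD through it), never on
individual correlation pixels.

## 3. Synthetic scattering planes

Planes are synthesized in the correlation domain so that the *analyzer's own
forward path* recovers the prescribed law:

- Radial target: annulus energy ∝ r^(−α) between an inner scale (1 µm) and an
  outer scale (120 µm), flat outside. Because annulus pixel counts on a
  discrete lag lattice are lumpy at small radii, the per-pixel target is the
  annulus energy divided by the *exact pixel count of that annulus* (bin
  width δr). Annulus sums then follow r^(−α) by construction rather than
  only in the continuum limit; without this normalization the recovered slope
  is biased by up to ~15% at small α.
- Roughness: the target is multiplied by seeded log-normal noise
  (σ = `noise_sigma`, default 0.2), point-symmetrized so the angular-domain
  result stays real. This provides realization-to-realization slope scatter,
  making "averaged over N seeds" recovery statements non-trivial.
- Random phase: the correlation-domain target is multiplied by exp(iφ) with
  φ drawn uniformly and antisymmetrized under k → −k. This leaves |FFT|
  (what the analyzer measures) exactly unchanged while converting the plane
  from a compact deterministic lobe into a delocalized speckle field with
  near-Gaussian pixel statistics — matching what a real coherent measurement
  looks like and exercising the artifact-masking path realistically.
- Inverse transform: the real part of the 2D IFFT is taken and the plane is
  shifted so its minimum is zero. Taking a magnitude here instead would
  corrupt the prescribed spectrum (|FFT(|IFFT(C)|)| ≠ C); the real part plus
  DC shift changes only the zero-lag pixel, which every fit excludes, so the
  prescribed law survives exactly. With `noise_sigma = 0` the recovered α
  equals the prescribed value to machine precision.

## 4. OCT B-scans, segmentation and registration

Synthetic B-scans place three bright bands (NFL, OPL, RPE) over a dim
background with the layout (top to bottom, in µm): 30 vitreous, NFL, 40 gap,
OPL, 50 gap, RPE, 30 below; thicknesses are per-record draws. The OCT axial
pixel is 2 µm (so an 18 µm NFL is 9 rows). Speckle is multiplicative
unit-mean exponential noise mixed at `speckle_level` (cohort default 0.3).

`segment_layers` median-filters laterally (width 11), finds per-column
intensity peaks (`scipy.signal.find_peaks`, prominence ≥ 25% of the column
range), refines band edges at raw-gradient extremes within ±12 rows, and
takes the per-boundary column median. Columns failing detection are dropped;
if fewer than half the columns or the wrong number of bands survive, a
`SegmentationError` is raised (the caller logs the record as a drop). On
noiseless phantoms recovery is exact; at speckle 0.3 the mean absolute
boundary error stays well under one pixel because of the median-of-columns
estimate.

Registration maps OCT row intervals to a/LCI depth pixels through physical
depth: `pixel_alci = round(row_oct · 2 µm / 10 µm)` with round-half-away-
from-zero, half-open [top, bottom) intervals, a minimum mapped width of one
pixel, and clamping to the volume depth (with a warning). Layer thickness is
`(bottom − top) · oct_axial_pixel`. The layer's angular plane is the
element-wise mean of the mapped depth planes.

## 5. Specular-artifact masking

The optical artifact modeled is a saturating reflection (e.g. from the
crystalline lens): a compact disc several times brighter than the tissue
scattering level. Detection is multiplicative — pixels above 5× the plane
median, grouped into connected components, components smaller than 4 pixels
discarded, survivors dilated by 2 pixels. A dispersion-based threshold
(k·σ or k·MAD) is deliberately *not* used: it trims legitimate speckle-tail
pixels, and because tail mass varies with the medium's correlation slope,
such trimming biases intensity statistics differently across groups (in
testing it produced ~40% spurious variance significance between groups with
identical generated variance). A user-supplied mask overrides the automatic
rule. Planes with more than 50% excluded pixels are flagged and dropped.

## 6. Intensity statistics

For each registered, masked plane the retained pixels define an intensity
histogram (k pixels per bin, N total); the reported moments — mean,
population variance (divisor N), skewness, excess kurtosis — are computed by
direct summation over the retained pixels, which equals the k/N histogram
formula with singleton bins and avoids binning bias. Records with fewer than
100 retained pixels are dropped. Group-normalized displays (values divided by
the control-group stratum mean) are provided for reporting; normalization is
affine and provably does not alter any test statistic.

## 7. Cohort design and repeated-measures inference

A cohort is two groups of eyes (default 10 WT vs 13 AD), each measured at 8
retinal locations: 4 at 500 µm and 4 at 1000 µm from the optic nerve head
along the superior / inferior / nasal / temporal axes (locations on the
vertical axis belong to the superior/inferior quadrants used for subset
analyses).

Within-eye dependence is compound symmetry: location deviations of a metric
share a common correlation ρ. Sampling uses the exact construction
`x = √(1−ρ)(z − z̄) + √(1+(k−1)ρ)·z̄` on i.i.d. normals z, valid for the
admissible range −1/(k−1) < ρ < 1. Note that for k = 8 the lower bound is
−1/7 ≈ −0.1429: a reported correlation of exactly −1/7 sits on the
singular boundary of the compound-symmetry family, so the package default is
ρ = −0.14, just inside it. `CohortSpec` rejects inadmissible values.

Group effects (defaults; each drawn per eye with the stated SD around the
group mean):

| layer | parameter      | WT mean | AD mean | SD   |
|-------|----------------|---------|---------|------|
| NFL   | α              | 0.8     | 1.0     | 0.12 |
| OPL   | α              | 0.8     | 1.0     | 0.12 |
| RPE   | α              | 0.9     | 1.1     | 0.12 |
| NFL   | intensity mean | 5.0     | 6.5*    | 0.5  |
| NFL   | pixel variance | 1.0     | 1.4     | 0.15 |
| NFL   | thickness (µm) | 18      | 16      | 1.2  |

(*) the AD intensity-*mean* elevation applies only in the superior quadrant
(`ad_intensity_mean_quadrants`); the variance elevation is quadrant-uniform.
Mean and variance levels are parameterized separately because a single
multiplicative brightness factor could not express a mean effect confined to
one quadrant together with a quadrant-uniform variance effect. All other AD
parameters equal WT. Per-record planes are built as `M + √V·u` where u is
the standardized synthetic speckle plane, clipped at zero (negligible at the
default operating point, ≈4.5 SDs from zero).

Inference for each (metric, layer): in the balanced design the exact nested
(repeated-measures) ANOVA

    F = MS_group / MS_eye(group),  df = (1, n_eyes − 2)

with the compound-symmetry correlation estimated from variance components,

    ρ̂ = (MS_eye − MS_within) / (MS_eye + (k − 1)·MS_within),

allowed to go negative. Unbalanced designs (after drops) collapse to eye
means and use a Welch two-sample test (F = t²). Assumption screens:
Shapiro–Wilk on within-eye residuals at a Bonferroni-style α = 0.003, and
the Brown–Forsythe (median-centered Levene) test on eye means at α = 0.05.
Quadrant-subset analyses rerun the same test on the records of the named
quadrants only.

## 8. Drops and conservation

Per-record failures never abort a cohort run; they become logged drops with
reasons: `segmentation_failure`, `mask_overexclusion` (>50% masked),
`insufficient_pixels` (<100 retained), `missing_scattering_data`. The
invariant `generated = analyzed + dropped` holds on every run, including
fault-injection runs, and is recorded in the run manifest.

## 9. Determinism and seeds

One master seed drives a run. Child seeds for each (eye, location, stage)
derive from `numpy.random.SeedSequence([master, eye_index, location,
stage])`, so any record can be regenerated in isolation and partial reruns
are stable. Pipeline outputs (metrics/stats/drops CSVs, report) are
byte-identical across runs with the same seed.

## 10. What the synthetic data does and does not emulate

Emulated: the power-law correlation structure of tissue scattering with
per-layer slopes, coherent-speckle pixel statistics, layered OCT geometry
with multiplicative speckle, specular saturation artifacts, two-group eye
cohorts with compound-symmetric within-eye correlation, and record-level
data loss.

Not emulated: real instrument noise floors and spectrometer roll-off, eye
motion and blood-vessel shadows, wavelength-dependent scattering, partial
transverse coherence, anatomical curvature of retinal layers, and any
biological variability beyond the Gaussian per-eye parameter draws. Absolute
intensity units are arbitrary; only within-cohort comparisons are
meaningful.

## 11. Numerical notes

- All FFTs are `numpy.fft`; the correlation map uses `fftshift` so the
  zero-lag pixel is at (n/2, n/2) for even n.
- Annulus binning uses `numpy.bincount` on floor(r/δr) indices; empty annuli
  are dropped rather than interpolated.
- Log-log fitting uses `numpy.polyfit` degree 1 on base-10 logs; bins with
  zero energy are excluded; at least 4 bins are required.
- Moments use direct compensated sums over retained pixels (divisor N);
  two-point and constant distributions have well-defined conventions
  (skewness/kurtosis of a constant plane are 0).
- ANOVA sums of squares are accumulated exactly as written in §7;
  p-values come from `scipy.stats` (F, t, Shapiro–Wilk, Levene).
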