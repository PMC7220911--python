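# retscat

Light-scattering analysis of co-registered retinal OCT + a/LCI data, with a
full synthetic data generator and cohort-level statistics.

Angle-resolved low-coherence interferometry (a/LCI) records depth-resolved 2D
angular distributions of light scattered by tissue. The Fourier transform of
an angular distribution is the two-point spatial correlation of the optical
field, so each retinal layer yields a radial correlation-energy curve whose
log-log slope α over a 2–10 µm window summarizes sub-cellular texture
(fractal dimension FD = 3 − α). Co-registered OCT B-scans provide the layer
boundaries (nerve fiber layer, outer plexiform layer, retinal pigmented
epithelium) that select which depths of the a/LCI volume belong to each
layer. Per-layer intensity histograms supply complementary statistics (mean,
variance, skewness, excess kurtosis). Group differences between cohorts of
eyes (e.g. wild-type vs an Alzheimer's-model strain) measured repeatedly at
8 retinal locations are tested with an exact nested repeated-measures ANOVA
under compound symmetry, with quadrant-restricted subset analyses.

Because real instrument data are not distributable, the package includes
generators for every input it consumes — raw spectral scans, angular
scattering planes with a prescribed correlation power law, speckled layered
B-scans, and whole two-group cohorts — all with exact ground truth, so every
stage of the analysis is verifiable against known answers. See
[docs/methods.md](docs/methods.md) for the model, conventions and defaults.

## Worked example

Simulate the default study design (10 wild-type vs 13 AD-model eyes, 8
locations per eye), run the entire pipeline — spectral processing, OCT layer
segmentation, OCT→a/LCI registration, specular masking, correlation-slope
and intensity metrics, repeated-measures tests — and print the report:

```python
from retscat import RunConfig, run_pipeline

config = RunConfig(master_seed=7)
run = run_pipeline(config)
print(run.report())
```

Output (excerpt; the full report covers 6 metrics × 3 layers × 3 subsets):

```
Cohort analysis report
============================================================
records generated=184 analyzed=184 dropped=0 (conservation OK)

             alpha  NFL [         all] effect(AD-WT)=+0.18963 F=961.3 p=5.065e-19 * rho_hat=-0.1291
             alpha  OPL [         all] effect(AD-WT)=+0.20067 F=2403 p=3.829e-23 * rho_hat=-0.1349
             alpha  RPE [         all] effect(AD-WT)=+0.20458 F=1094 p=1.333e-19 * rho_hat=-0.1272
    intensity_mean  NFL [         all] effect(AD-WT)=+0.38849 F=1310 p=2.078e-20 * rho_hat=-0.1414
    intensity_mean  NFL [    superior] effect(AD-WT)=+1.7088 F=141.7 p=8.446e-11 * rho_hat=+0.0057
    intensity_mean  NFL [    inferior] effect(AD-WT)=+0.012935 F=0.007645 p=0.9312 rho_hat=-0.1475
    intensity_mean  OPL [         all] effect(AD-WT)=+0.0027134 F=0.1754 p=0.6796 rho_hat=-0.1412
intensity_variance  NFL [         all] effect(AD-WT)=+0.39942 F=1.393e+04 p=3.996e-31 * rho_hat=-0.1399
      thickness_um  NFL [         all] effect(AD-WT)=-1.9192 F=525.1 p=2.431e-16 * rho_hat=-0.1165
```

The default generator encodes the effect pattern the analysis is designed to
detect: a thinner AD nerve fiber layer, higher correlation slope α in all
three layers, and higher NFL scattering intensity mean and variance — with
the mean elevation confined to the superior quadrant (significant in the
`superior` subset, null in `inferior`) while the variance elevation is
quadrant-uniform. Layers with no generated intensity effect (OPL, RPE) test
null. A starred row is significant at α = 0.05; `rho_hat` is the estimated
within-eye compound-symmetry correlation across the 8 locations.

`run_pipeline(config, outdir="out/")` additionally writes `metrics.csv`,
`stats.csv`, `drops.csv`, `report.txt`, `manifest.json` and the serialized
`config.yaml`. Runs are byte-identical given the same master seed.

### Command line

The same pipeline is available as a CLI, either end-to-end or staged through
an HDF5 container:

```
retscat run --seed 7 --out out/                 # end-to-end
retscat simulate --seed 7 --out study/          # writes study/data.h5 + truth.csv
retscat metrics --in study/ --window 2:10       # segment, register, measure
retscat stats --in study/ --quadrants superior,inferior
retscat report --in study/
```

### Library building blocks

```python
import numpy as np
from retscat import (OpticalConfig, MediumSpec, make_angular_plane,
                     angular_to_correlation, azimuthal_integrate, fit_slope)

cfg = OpticalConfig()                    # 128x128 angles, 1 um lag pixel
plane = make_angular_plane(MediumSpec(alpha_true=1.2, seed=0), cfg)
curve = azimuthal_integrate(angular_to_correlation(plane, cfg))
fit = fit_slope(curve, window=(2, 10))
print(fit.summary())
# power-law fit on [2, 10] um: alpha = 1.1580, FD = 1.8420, R^2 = 0.9978 (8 bins)
```

## Package layout

| module | contents |
|---|---|
| `retscat.config` | acquisition geometry, lag/depth conventions, validation |
| `retscat.spectral` | raw spectra → depth profiles → scattering volumes |
| `retscat.layers` | B-scan segmentation, OCT→a/LCI registration, specular masking |
| `retscat.correlation` | 2D correlation, azimuthal integration, power-law fits |
| `retscat.intensity` | masked histogram statistics, group normalization |
| `retscat.cohort` | nested RM-ANOVA, ρ̂, assumption screens, quadrant subsets |
| `retscat.synthetic` | all generators (planes, scans, B-scans, cohorts) |
| `retscat.io` | HDF5 cohort container, boundary/metric CSVs |
| `retscat.pipeline` | run orchestration, drop accounting, reports |
| `retscat.cli` | `retscat` command group |
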