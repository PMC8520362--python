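# sonokr

Kernel-regression reconstruction of 3D freehand ultrasound volumes, with a
digital phantom of the anal sphincter complex (ASC), clock-face thickness
morphometry, and two-group statistics for delivery-mode comparisons.

## The problem

Transperineal 3D ultrasound of the postpartum pelvic floor yields scattered,
noisy intensity samples rather than a regular volume.  Clinical questions —
e.g. whether vaginal delivery thins the internal anal sphincter (IAS),
external anal sphincter (EAS) or puborectalis muscle (PRM) relative to
Caesarean section — require (1) reconstructing a regular voxel volume from
the scattered samples, (2) measuring wall thickness at standardized
clock-face positions on three axial planes, and (3) comparing the two
delivery groups site by site.  `sonokr` implements that pipeline end to end
and validates it on an analytic phantom with known ground truth.

## The estimator

Observations are modeled as noisy samples of an unknown smooth intensity
field:

    Y_i = r(X_i) + eps_i,    i = 1..P

with `X_i` in R^3 (mm).  Around a query point `X`, `r` is expanded in a
Taylor polynomial of order `N` and fitted by weighted least squares

    beta_hat = argmin_beta sum_i K_h(X_i - X) * (Y_i - Phi(X_i - X) beta)^2

where `Phi` collects the centered monomials up to degree `N` (1, 4 or 10
columns for N = 0, 1, 2) and `K_h(u) = exp(-||u||^2 / 2h^2)` is an isotropic
Gaussian kernel of bandwidth `h`.  The intercept `beta_0` is the estimate
`r_hat(X)`.  N = 0 is the Nadaraya-Watson weighted mean; the package default
is N = 1 (local linear).  Evaluating `r_hat` at every voxel center of a
regular grid produces the reconstructed volume.

The estimator is exposed as a scikit-learn regressor:

```python
from sonokr import KernelRegression3D
model = KernelRegression3D(bandwidth="auto", order=1).fit(X, y)   # X: (P, 3)
values = model.predict(query_points)                              # NaN = no support
```

## Worked example

```python
import numpy as np
from sonokr import (PhantomSpec, VoxelGrid, KernelSpec, IntensityModel,
                    MorphometryConfig, make_phantom, sample_cloud,
                    reconstruct_volume, measure_complex, default_bandwidth)

spec = PhantomSpec(seed=1)                      # IAS 2 mm, EAS 2 mm, PRM 7 mm
truth = make_phantom(spec)
cloud = sample_cloud(truth, n=200_000, noise_sd=0.0, seed=1)
grid = VoxelGrid.from_box(*spec.box, spacing=0.2)
vol, report = reconstruct_volume(
    cloud, grid, KernelSpec(bandwidth_h=default_bandwidth(cloud), order_N=1))
table = measure_complex(
    vol, MorphometryConfig(intensity_model=IntensityModel(levels=spec.intensities)))
print(table[table.structure == "PRM"])
```

prints

```
   structure plane  clock  thickness_mm
16       PRM   mid      4          7.02
17       PRM   mid      8          7.01
```

— the puborectalis sling, specified at 7.00 mm, recovered to within half a
voxel (0.1 mm) at both of its 4 and 8 o'clock sites; the other 16 sites of
the protocol (IAS at 3/6/9/12 on the proximal, mid and distal planes, EAS at
3/6/9/12 distally) behave the same.

Group comparison from published summary cells (mean ± SD, n per group):

```python
from sonokr import load_reference_tables, compare_table
report = compare_table(load_reference_tables())
print(report.loc[report.site == "EAS_distal_12",
                 ["site", "t", "p_printed_style", "significant"]])
```

```
            site          t p_printed_style  significant
19  EAS_distal_12 -12.070888           <0.01         True
```

A `sonokr` command-line tool wraps the same pipeline
(`sonokr simulate | reconstruct | measure | compare | pipeline`); see
`sonokr --help`.

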