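# Methods

## Model and estimator

The reconstruction treats the acquired ultrasound samples as noisy
observations `Y_i = r(X_i) + eps_i` of a smooth intensity field `r` over
patient space (mm; x = patient left, y = anterior, z = cranial — the frame
is a package convention).  At a query point `X` the field is approximated by
its Taylor polynomial of order `N` and fitted by weighted least squares,
each sample weighted by an isotropic Gaussian kernel of its distance to
`X`; the fitted intercept is the field estimate.  The kernel is used
unnormalized (`exp(-||u||^2/2h^2)`): any positive constant cancels in the
fit.  Its bandwidth `h` is a scalar — a full 3x3 bandwidth matrix adds
nothing when sampling is statistically isotropic, which the acquisition
model here is.

Assumptions: `r` is locally smooth at the kernel scale (true for a
band-limited imaging system); noise is additive, zero-mean and independent
across samples; sampling is dense enough that a typical kernel support
holds several times the basis size of samples.

### Polynomial order

Orders 0 (Nadaraya-Watson mean), 1 (local linear) and 2 (local quadratic)
are supported; the default is 1.  Order 1 is the smallest basis that removes
the order-0 boundary/gradient bias, and its 4-coefficient fit is the variant
for which the normal-equation structure is concretely fixed throughout the
package; order 2 costs ~6x and mainly helps when curvature at the kernel
scale is strong.  Exact reproduction of degree-<=N polynomial fields is the
core correctness property and is tested at all three orders.

### Numerical scheme

Per query point the weighted normal equations `(Phi' W Phi) beta = Phi' W y`
are solved directly; the matrix is at most 10x10.  Queries are processed in
chunks: neighbor pairs within the truncation radius come from a kd-tree
(`scipy.spatial.cKDTree.sparse_distance_matrix`), per-query Gram matrices
are accumulated with `bincount` reductions, and the small systems are
solved batched.  Chunking changes only floating-point summation order
(differences at the 1e-15 level); record order likewise.  If a plain solve
fails (rank-deficient neighborhood, e.g. collinear samples), a Tikhonov
term `ridge_eps x trace` (default 1e-10) is added — only then, so the
regularizer never perturbs well-posed fits.

Neighborhoods are truncated at `3h` (the omitted Gaussian mass is < 1e-4 of
the central weight).  Sparse neighborhoods degrade the order (2 -> 1 -> 0)
when fewer than `basis size + 2` neighbors are available; a voxel with no
neighbor in support is reported as missing (NaN plus an explicit mask), a
value rather than an error.

### Bandwidth

Default `h = 1.5 x median nearest-neighbor distance` of the cloud.  The
factor keeps the expected neighbor count inside the support roughly constant
(~50-60 for uniform sampling) regardless of density, comfortably above the
order-1 basis size while staying well below the 2 mm wall scale at the
sampling densities the phantom studies use (h ~ 0.44 mm at 200k samples in
the default box).

## Phantom

The synthetic anatomy is an analytic piecewise-constant field: an IAS ring
(inner radius 5 mm, wall 2 mm) along the whole 30 mm canal; an EAS ring
(2 mm) abutting the IAS outer wall in the distal z band (0.1-0.3 of canal
length); a PRM sling (7 mm) abutting the IAS outer wall in the mid band
(0.4-0.6).  Wall defaults echo the reported postpartum magnitudes (IAS ~2,
EAS ~1-3, PRM ~7 mm).  The sling subtends 210 degrees centered posteriorly:
open anteriorly like the anatomy, and wide enough that its free ends stay
clear of every measurement ray — a sling ending knife-edge exactly on the
3/9 o'clock axis would put an r-dependent partial-volume mixture on those
rays and bias the mid-plane IAS measurement by up to ~0.25 mm.

Intensity levels (arbitrary units, range 100): background 0, EAS 40, IAS
70, PRM 100.  Distinct levels per tissue are what make boundaries between
abutting structures well defined; the ordering puts the largest contrast on
the structure with the largest wall.  Sampling is uniform over the bounding
box by default (a `sweep` mode emulates a freehand fan of jittered
transverse planes); values are the field plus i.i.d. Gaussian noise — the
standard reading of independent identically distributed additive error —
of SD `noise_sd` (default 10, i.e. 10% of the range).

What the phantom does not emulate: speckle statistics (multiplicative,
correlated), attenuation and shadowing, probe-pressure deformation,
anatomical asymmetry and defects.  Passing the end-to-end tests therefore
shows the reconstruction-morphometry chain is correct and
resolution-limited, not that clinical measurements would carry the same
error bars.

## Morphometry

Planes: axial slices at fractions 0.8 / 0.5 / 0.2 (proximal / mid / distal)
of the volume's z extent, slice index `floor(fraction x (nz - 1))`.
Clock-face convention: 12 o'clock anterior (+y), 3 o'clock patient-left
(+x), clockwise viewed from caudal; ray angle `90 - 30 x clock` degrees.

A wall's edges along a ray are placed where the intensity crosses the
half-way level between the structure's level and the flanking tissue's
level — the full-width-at-half-maximum rule when the neighbor is
background, generalized to abutting tissues.  For any edge blurred by a
symmetric point-spread function the half-way crossing coincides with the
true boundary, which is what makes the rule parameter-free.  Thickness is
measured along the ray; for the centered rings of the phantom this equals
perpendicular wall thickness.

Implementation choices, in order of the failure they prevent:

* **Empirical plateaus.** Regions along the ray are identified as
  low-gradient runs (|dI/dt| <= 15% of the intensity range per mm, length
  >= 0.5 mm) rather than by proximity to nominal levels, because the smooth
  transition between two tissues passes through values that can mimic a
  third tissue, and because a ray grazing a structure's angular edge sees a
  partial-volume mixture matching no nominal level at all.  A plateau whose
  level sits within a quarter-gap of a nominal level counts as that tissue
  and contributes its *nominal* level to the half-way rule (a thin wall's
  crest is slightly eroded by smoothing; its true level is not); an
  out-of-band plateau contributes its *measured* level, the only meaningful
  baseline for a mixture.  If a thin wall flanked by two high-amplitude
  edges keeps a gradient above the bound across its whole crest, the bound
  is escalated deterministically (x2, x4) until the wall shows a plateau.
* **Lumen-based center.** The ring center is the centroid of the canal
  lumen (the connected background component containing the IAS annulus
  centroid), not of the annulus mask itself: transition pixels cast by an
  abutting structure (the PRM sling) bias the annulus centroid by ~2 mm
  posteriorly on the mid plane, and an off-center origin makes every ray
  cross the walls obliquely (+3% thickness per (offset/radius)^2).
* **Sector pooling.** Each clock position names a 30-degree sector; the
  reported thickness is the median over rays spanning +/-15 degrees (step
  3) and +/-2 mm axially (step 0.5).  Reconstruction error is spatially
  correlated at the bandwidth scale, so a single ray carries ~0.1 mm of
  edge-localization error that averaging within one correlation length
  cannot remove; the pooled bundle spans several correlation lengths in
  both directions and brings the per-site error under half a voxel at the
  reference sampling density.  On a wall of constant thickness pooling does
  not shift the expected value.

Measurements are reported in mm to 2 decimals, the precision of the
clinical tables.

## Group statistics

Per-site independent two-sample t-tests, computable from raw values or
directly from (mean, SD, n) summaries; the default is Welch's unequal-
variance statistic with Welch-Satterthwaite degrees of freedom (the safer
default when only "independent-sample t-test" is specified; with the
near-balanced reference groups Welch and pooled differ by < 5% on every
cell, which is tested).  Sign convention: group 1 (vaginal delivery) minus
group 2 (Caesarean).  No multiple-testing correction is applied, mirroring
the reference analysis, which reports raw per-site p-values at alpha =
0.05; the package reproduces that report, it does not endorse the
inferential choice.  P-values below 0.01 render as "<0.01" in printed-style
output.

The published summary tables ship as a data fixture.  Two of their cells
are internally inconsistent — the printed statistic cannot follow from the
printed mean/SD/n under any standard two-sample t-test (age: printed t 0.4
vs recomputed 1.41; EAS distal 6 o'clock: printed -0.48 vs recomputed
5.79).  `compare_table` flags consistency automatically at a threshold of
0.3 on ||t| recomputed - |t| printed|, which separates the populations by
an order of magnitude (consistent cells deviate by at most 0.11); the
flagged cells are reported but excluded from printed-value comparisons.

The Monte-Carlo harness (`simulate_two_group_study` plus the studies in
`sonokr.studies`) checks calibration: type-I error at the reference group
sizes (n = 77/80) stays within 0.05 +/- 0.02 over 2000 replicates, and the
largest reported effect (EAS distal 12 o'clock, 1.04±0.27 vs 1.87±0.55) is
detected in >99% of replicates.

## Study sizes and runtime

The reference end-to-end study uses 200,000 samples reconstructed at 0.2 mm
voxels (~3.9M voxels, ~60 neighbors per voxel), about a minute on one CPU;
the PSNR comparison uses a 0.5 mm evaluation grid, which is ample for a
volume-level mean-squared-error metric.  These sizes are the package's
reference conditions: halving the sampling density roughly doubles the
bandwidth and visibly degrades thickness recovery (the 2 mm walls approach
the resolution limit), which is the expected scaling, not a defect.

## Known limitations

* The FWHM rule assumes two resolvable edges; walls thinner than ~2
  bandwidths merge into a single crest and are reported via the escalated
  plateau search with reduced accuracy, or as missing.
* Missing-voxel handling is per-voxel; no inpainting is attempted.
* The nearest-neighbor baseline is intentionally naive (no averaging), as a
  floor for PSNR comparisons.
* `estimate_point` rebuilds the spatial index per call; use
  `KernelRegression3D` directly for repeated queries.
* Volume I/O supports axis-aligned geometries only (diagonal affine).
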