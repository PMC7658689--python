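# Methods

## The model

OCT image contrast comes from backscattering, but the measured A-scan
intensity decays with depth because the probing beam is attenuated by all
the tissue above. Under a single-scattering model, the beam reaching depth
`z` has been attenuated by `exp(-2 * sum_{u<z} mu(u) dz)` (the factor 2
accounts for the double pass), and the fraction backscattered at `z` is
proportional to the local attenuation coefficient `mu(z)`. Two
depth-resolved quantities then follow from the measured profile `E_A(z)`
alone, with no per-layer fitting:

* **Corrected intensity** `E_R(z) = E_A(z) * S / T(z)`, where `S` is the
  total A-scan sum and `T(z) = sum_{u>z} E_A(u)` is the tail sum. This
  removes the depth decay, so `E_R >= E_A` wherever defined.
* **Attenuation coefficient** `mu(z) = E_A(z) / (2 dz T(z))`, in 1/µm when
  `dz` is the axial voxel pitch in µm.

The tail-sum inversion is exact in the continuum limit when (a) only
singly-scattered light contributes, (b) the backscattered fraction is
proportional to `mu`, and (c) the signal is fully attenuated within the
recorded depth range. Assumption (c) fails at the bottom of any real scan,
which is why the estimate is biased upward near the last voxels: the tail
sum misses the signal below the grid. The estimation band is therefore
restricted per column to `[z_ILM, z_RPE-lower + 300 voxels]`: everything
above the inner limiting membrane is instrument noise and is zeroed before
the tail sums are formed, and the band stops a fixed extension (default
300 voxels ≈ 786 µm) below the RPE, deep enough to cover the choroid.
Voxels whose tail sum is zero are flagged invalid rather than clipped, and
never enter regional means.

Two conventions for `dz` circulate: physical units (`dz = 2.62` µm,
default) and raw voxel units (`dz = 1`), which reproduces the literal
"local intensity over twice the tail sum" arithmetic. Both are reachable
through the `dz` parameter; all shipped defaults use physical units.
The point-spread function and sensitivity roll-off of the instrument are
*not* corrected (no `P(z)S(z)` division); the estimator therefore
overstates `mu` slightly, identically for all subjects.

## Discretisation error

On a discrete grid with constant `mu`, the estimator converges to
`(exp(2 mu dz) - 1) / (2 dz)` rather than `mu` — a relative bias of about
`mu dz` (0.26% at `mu = 0.001`/µm, `dz = 2.62` µm). Together with the
residual-tail bias this is why the correctness tests assert 2–3%
tolerances rather than exactness, and why they are evaluated away from the
last voxels of the grid and from layer interfaces.

## Synthetic phantoms

The phantom generator inverts the same model it feeds: each voxel's
noiseless intensity is `alpha * mu * dz * I0 * exp(-2 * cumulative optical
depth)`. Because the backscatter coupling `alpha` is constant across
layers, the tail-sum estimator is unbiased for the phantom (up to the
discretisation terms above), which makes forward-then-invert a proper
oracle. Layer geometry: a seven-layer stack (vitreous, RNFL, GCIPL, an
outer-retina block, RPE, choroid, sub-choroidal tissue) with per-layer
mean thickness, a smooth lateral Gaussian-field thickness variation, and a
radially symmetric Gaussian foveal pit in RNFL and GCIPL. Defaults:
thicknesses follow healthy macular anatomy (RNFL 38.8 µm, GCIPL 77.8 µm,
pit depths 30/60 µm with 0.5/0.4 mm radii), `mu` in the 1e-3/µm range with
a strongly scattering RPE (0.005/µm) and a scleral-like 0.003/µm below the
choroid — the latter chosen so the in-grid signal is nearly fully
attenuated and the retina-band estimates carry only ~1–2% residual-tail
bias. Speckle is multiplicative unit-mean gamma noise with shape `L = 4`;
its sample mean converges to the noiseless profile, so it is reducible by
any averaging-type filter.

The default grid is the acquisition geometry (992 × 512 × 256 voxels at
2.62 × 11.72 × 23.44 µm). `PhantomSpec.desk()` keeps the native axial
sampling but coarsens the lateral grid to 64 × 64 columns at 93.76 µm,
preserving the ~6 × 6 mm field of view so the 5-mm quadrant square still
fits; tests and the acceptance script run at this scale (with 8–24 columns
where only axial behaviour matters).

What the phantoms deliberately do **not** model: realistic speckle
correlation, the confocal PSF and sensitivity roll-off, vascular shadows,
eye motion, segmentation error. Passing tests therefore demonstrate the
estimators and the regional/statistical machinery, not robustness to
instrument physics absent from the forward model.

## Cohort simulation

`metrics` mode draws each subject's per-layer, per-region indices
independently from group-wise Gaussians whose means and SDs default to the
published patient/control summary table (38 patients, 43 controls). This
reproduces the marginal structure of that table but not the within-subject
correlation between quadrants or indices, and the "average" region is
drawn as its own variable rather than derived from the quadrants. `image`
mode draws per-subject layer thickness and attenuation from the overall
targets and bakes them into a per-subject phantom, so pipeline-derived
metrics have expectations near the targets (with the small positive
estimator bias noted above).

A consequence of simulating from the printed summaries: comparisons whose
printed effect sizes are small behave accordingly. The overall GCIPL
thickness difference (76.37 ± 6.88 vs 77.76 ± 4.87, d ≈ 0.23) is rejected
at the 5% level in roughly one cohort in five, so any joint "significance
pattern" event that conditions on its non-significance cannot occur in
more than ~81% of seeds. The pattern-rate numbers the test suite and the
acceptance script print should be read with that ceiling in mind.

## Statistics

* Normality gate: Shapiro–Wilk in each group; the Student unpaired t-test
  (Welch by flag) runs only when both groups pass at the same alpha
  (default 0.05), otherwise the Mann–Whitney U test with normal
  approximation, continuity and tie correction. Constant samples are
  degenerate for Shapiro–Wilk and fall through to the rank test.
* Standardized beta: slope of z-scored response on z-scored predictor,
  equal to the Pearson correlation in simple regression; two-sided P from
  the t distribution with n − 2 df.
* AUC via the Mann–Whitney identity, ties counting one half; each index is
  oriented so its AUC is at least 0.5 and the orientation is reported.
* DeLong: placement values per subject give the variance of each AUC and
  the covariance between two AUCs scored on the same subjects; the paired
  difference uses a z-test, confidence intervals are Wald on the AUC scale
  truncated to [0, 1].
* No multiple-testing correction by default; Holm step-down available by
  flag.
* Report pairing: per layer, the two indices significant against AUC = 0.5
  with the largest AUCs are compared pairwise (fallback: the two largest).

## Numerical and design choices

* Axial convention: z = 0 at the vitreous, increasing with depth; tail
  sums exclude the current voxel (`u > z`), written as half-open 0-based
  ranges in code.
* Tie-break for quadrant midlines: columns exactly on a dividing line go
  to the superior / nasal side. The "average" region is the grand mean
  over all in-square columns (voxel-count-weighted), not the mean of the
  four quadrant means.
* Flattening uses integer-voxel shifts only, so 16-bit intensities are
  preserved exactly and metrics computed from consistently shifted
  surfaces are invariant — exactly so when nothing nonzero is shifted off
  the grid, and to ~0.1% otherwise (the truncated deep tail).
* Fovea localisation (unspecified upstream): minimum of the 3 × 3-smoothed
  inner-retina thickness map; multiple disjoint minima, or a minimum
  region covering more than 5% of columns (no pit), demand an explicit
  centre override.
* Volume files preserve the array dtype (uint16 round-trips as 16-bit
  TIFF; float32 phantoms as float32 TIFF) because quantizing the weak deep
  signal to integers corrupts the tail sums the estimator divides by.
* The choroid extension "300" is interpreted as voxels (≈ 786 µm) and is
  configurable.

## Problem sizes

Tests and the acceptance script use: 1400–2000-voxel A-scans for estimator
correctness, 20 integer-valued 50 × 20 B-scans for exact oracle
equivalence, 2000 replicate cohorts (n = 38/43) for type-I calibration,
10,000 bootstrap replicates for the DeLong SE cross-check, and 100–200
seeded cohorts for the power and pattern rates.
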