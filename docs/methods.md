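# Methods

This note documents the model, parameter choices and numerical conventions
implemented in `mrhotspot`. Nothing here claims empirical results beyond what
the test suite and `scripts/acceptance.py` actually compute.

## Data model

All volumes live on an axis-aligned rectilinear `Grid` (shape, voxel size in
mm, origin in mm, RAS orientation). A `ScalarMap` carries float64 values, a
unit tag (`ms`, `ratio`, `ppm`, `unitless`) and an explicit boolean *domain*
marking where the map is defined; undefined voxels are stored as NaN on disk
(NIfTI, via nibabel) and excluded from every statistic. `BinaryMask` supports
union / intersection / difference / subset with strict grid-compatibility
checks — mixing grids is an error, never a silent resample.

NIfTI inputs are canonicalized to RAS; 4-D images and oblique (non-axis-
aligned) affines are rejected rather than approximated.

### Resampling

The analysis grid is the grid of the first MRSI map (the modality with the
coarsest native resolution, 3.4 mm isotropic in the default phantom); all
other maps and masks are resampled onto it. Scalar maps use trilinear
interpolation (`scipy.ndimage.map_coordinates`); undefinedness propagates by
interpolating an indicator of the undefined set and marking any target voxel
with interpolated indicator above 1e-9 as undefined, so a defined output value
never draws on an undefined input. Masks use nearest-neighbour only, which
preserves binarity. Resampling between grids with disjoint spatial extents is
an error.

## Regions of interest

Given a tumor segmentation TU and a white-matter mask WM on the analysis
grid:

* **TU+PT** = TU dilated by `dilation_voxels` (default 6) single-voxel,
  face-connected (6-neighbour) iterations. On a 3.4 mm grid, 6 iterations add
  a layer extending 20.4 mm ≈ 2 cm from TU along each axis, which is the
  intended peritumoral margin.
* **PT** = TU+PT \ TU.
* **NAWM** = (WM \ TU+PT) eroded once, to avoid partial-volume voxels at the
  region boundary contaminating the reference.

Morphology uses `scipy.ndimage` binary operations. Dilation is clipped at
the grid boundary (no wraparound). Erosion treats the outside of the grid as
foreground (`border_value=1`), making it the exact dual of clipped dilation;
this keeps the closing property (erode(dilate(m)) ⊇ m) valid at grid edges.
An empty TU or an empty derived NAWM raises `EmptyRegionError` — the analysis
has no meaningful reference in that case.

`RoiSet` checks its invariants (TU ⊆ TU+PT, PT = TU+PT \ TU, NAWM disjoint
from TU+PT) on construction.

## MRSI quality control

A voxel of a metabolite map is accepted when all of the following hold
(`QualityRule` defaults):

| Check | Default | Rationale |
|---|---|---|
| linewidth (tCr FWHM) | ≤ 0.15 ppm | broad lines → unreliable fits |
| tCr SNR | ≥ 5 | noise floor |
| metabolite CRLB | ≤ 80 % | fit uncertainty bound |
| spectral-fit coefficient | within 13 MAD of the median | gross fit outliers |

The FWHM rule discards *high* linewidth by default (`discard_high_fwhm=True`,
configurable). When the MAD of the fit-coefficient distribution is exactly 0
(constant map), the MAD rule rejects nothing — a zero scale makes every
deviation "infinite," and rejecting everything on a degenerate distribution
would be wrong.

A ratio voxel (e.g. Gln/tNAA) is defined only where both metabolites are
accepted and the denominator is strictly positive. A subject is unusable when
more than `max_undefined_fraction` (default 50 %) of TU+PT is undefined in
any ratio map; unusable subjects are excluded from cohort aggregation with a
logged warning.

## Hotspots

For map *m* and region *R*, the NAWM reference is the median of *m* over the
defined NAWM voxels, and the hotspot is

&nbsp;&nbsp;H(m, R) = { v ∈ R : m(v) > factor × median(m | NAWM) },

with strict inequality and default factor 1.5. An empty hotspot is legal (it
warns and is recorded as missing data, not as zero). `threshold_sweep`
evaluates a factor grid; hotspot size is non-increasing and the hotspot
median non-decreasing in the factor, and factor 0 recovers the whole defined
region — both properties are tested.

## Spatial similarity

* **DSC** = 2|A∩B| / (|A|+|B|); comparing two empty masks is an error rather
  than a conventional value.
* **Center of intensity** of mask A under map m: the m-weighted mean of the
  voxel-center positions, reported in cm (10 mm/cm). Negative weights are
  clipped to zero with a warning; a zero total weight or an undefined map
  voxel inside the mask is an error. **COID** is the Euclidean distance
  between two centers of intensity. COID is translation-invariant by
  construction (verified numerically).

## Cohort statistics

Subject-level observations are hotspot medians per (map, region), plus
un-thresholded NAWM medians. Cohorts are summarized as median (Q1, Q3) using
`numpy.percentile` with linear interpolation — the conventional choice, and
frozen so quartiles are reproducible. TU vs. PT contrasts use the two-sided
paired t-test (`scipy.stats.ttest_rel`) with pairwise deletion: a subject
missing either member of a pair (e.g. an empty hotspot) is dropped for that
map only. Fewer than 2 complete pairs is an error; zero variance of the
differences is flagged as degenerate (NaN p) rather than reported as an
infinite t.

## Phantom generator

`PhantomSpec` builds an ellipsoidal "brain" (semi-axes 0.88 × the field of
view by default), white matter = brain eroded 2 voxels, and an ellipsoidal
tumor whose default size and offset scale with the brain so small test grids
remain valid. The peritumoral shell is the tumor dilated with the same
morphology the pipeline uses. Each of the 10 maps (8 MRSI ratios, T1, T2) is
painted with per-region levels (defaults chosen as plausible glioma values,
e.g. Gln/tNAA 0.61 / 0.38 / 0.16 for tumor / shell / NAWM; T1
1724 / 1756 / 950 ms; T2 85.5 / 102.0 / 42.9 ms) and multiplied by
1 + cv·N(0,1) noise (default cv = 0.1), clipped at 0. An optional
infiltration-gradient mode ramps the shell linearly from the tumor level to
the NAWM level with distance.

Quality maps default to clean values (FWHM 0.06 ppm, SNR 20, CRLB 10 %);
defects are planted in random brain voxels at configurable fractions, and the
planted voxel sets are returned as ground truth, so QC recovery can be
checked exactly.

Cohorts draw per-subject seeds from `numpy.random.SeedSequence(master_seed)`;
between-subject biology is modelled as per-subject, per-map, per-region level
jitter, either absolute (`level_jitter_sd`) or relative (`level_jitter_rel`).
All derived integer seeds are kept below 2³¹.

### Realism and limits

The phantom is a piecewise-constant ellipsoid model: it has no partial-volume
mixing, no spatially correlated noise, no B0/B1 field structure, and
multiplicative Gaussian noise is only a first-order stand-in for
spectral-fit error distributions. It is designed to validate the *pipeline
mathematics* (region algebra, thresholding, similarity, statistics) against
known truth, not to emulate scanner physics.

## Statistical calibration

The paired TU-vs-PT test is calibrated by Monte-Carlo simulation through the
*real* pipeline stages (`simulate_tu_pt_hotspot_medians`): under a null with
equal planted TU and PT levels and between-subject jitter, the empirical
rejection rate at α = 0.05 over 1000 simulated 12-subject cohorts must lie in
[0.03, 0.07]; under the default (contrasted) levels, power at α = 0.01 must
exceed 0.90, cross-checked against the analytic noncentral-t computation.
The calibration grid (20 × 20 × 16 voxels, single map) was chosen for runtime
— it is the smallest grid on which the 6-iteration dilation still leaves a
non-empty NAWM — and its acceptance bands were fixed before the simulations
were run.

## Problem sizes

Default grid 64 × 64 × 39 at 3.4 mm isotropic (a plausible whole-brain MRSI
matrix). Tests and the acceptance script use reduced grids (32 × 32 × 24 for
recovery, 20 × 20 × 16 for calibration) purely for runtime; the code is
size-agnostic.

## Error handling

All package errors derive from `MrHotspotError` (`GridMismatchError`,
`VolumeFormatError`, `DisjointExtentError`, `EmptyRegionError`,
`QualityMapMissingError`, `ConfigError`). The CLI exits 2 for configuration
or usage errors and 1 for runtime failures.

## Limitations

* Only axis-aligned grids are supported; genuinely oblique acquisitions must
  be resliced upstream.
* No registration: MRSI and MRF volumes are assumed to share a spatial frame
  up to grid resampling.
* The hotspot threshold (1.5× NAWM median) is a fixed convention, exposed for
  sweeps but not optimized per subject.
* Cohort inference is a paired t-test on medians; no multiple-comparison
  correction across the 10 maps is applied (matching the tabular reporting
  style the pipeline mirrors).
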