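# Methods

This note records the models, conventions and numerical choices behind
each layer of the package, including the places where the underlying
methods admit more than one reasonable definition.

## Voxel morphometry

All morphometry operates on a `VoxelVolume`: a 3D boolean occupancy grid
with an isotropic voxel size in µm.  A voxel is treated as the closed
unit cube at its lattice site; voxel centers sit at integer + 0.5
coordinates.  Degenerate inputs (empty or full volumes, single-phase
grids) raise typed errors from the individual estimators;
`morphometry_summary` instead flags them and substitutes benign values so
batch runs over heterogeneous volumes of interest complete.

### Local thickness and spacing

Thickness follows the largest-inscribed-sphere definition: the local
thickness of a foreground voxel is the diameter of the largest sphere
fully contained in the structure that covers the voxel; `Th` is its mean
over the foreground and `Sp` is the same statistic on the complement
(so `mean_spacing(V) == mean_thickness(~V)` identically).  The
implementation is a granulometry on the Euclidean distance transform:
for candidate radii r descending in 0.5-voxel steps, voxels within
distance r of any point with inscribed radius ≥ r receive diameter 2r.
Distances are center-to-center, so a one-voxel plate reads ≈ 2 voxels —
the same convention as the brute-force sphere-painting oracle kept in
the test suite, which the implementation matches within 10% on balls,
slabs and tori.  The 0.5-voxel radius quantization bounds the cost at
two distance transforms per radius step and the error at one voxel of
diameter.

### Mean-intercept-length anisotropy

For each of n quasi-uniform directions (golden-angle spiral on the
sphere, default n = 512), a grid of parallel test lines (default spacing
6 voxels, jittered by a seeded offset; sampling step 1 voxel) is clipped
to the volume and sampled by nearest voxel.  MIL(ω) is the total
in-volume line length divided by the number of foreground/background
transitions between consecutive in-volume samples; directions with zero
crossings are dropped with a warning (a direction exactly parallel to a
set of uncrossed rods has no interface).  The points MIL(ω)·ω are
fitted by least squares with a centered quadric `pᵀAp = 1` (the cloud is
rescaled by its median MIL first for conditioning); the ellipsoid radii
are `1/√λᵢ` of the quadric eigenvalues and `DA = 1 − r_min/r_max`,
clamped to [0, 1].  Whether the historical index used radii or squared
radii (eigenvalues) is ambiguous; radii are the default and
`da_from="eigenvalues"` exposes the alternative, which compresses
mid-range values but shares both endpoints.  On a 128³ parallel-rod
lattice the estimator reads DA ≈ 0.97; on an isotropic random-sphere
pack at 30% volume fraction, DA ≈ 0.01.

### Euler characteristic and connectivity density

χ is computed exactly as V − E + F − C over vertices, edges, faces and
cells of the cubical complex of the closed-voxel union.  The closed-cube
union connects voxels sharing a face, edge or corner, i.e. 26-connected
foreground and 6-connected background; χ depends on this convention and
it is stated here because the complementary choice changes values on
thin structures.  The border correction Δχ uses mirror-tile sharing:
elements lying on the bounding box boundary are weighted 1/2 per
incident boundary plane (faces 1/2, border edges 1/4, corners 1/8), so
Δχ = χ_weighted − χ vanishes for structures away from the border.
Connectivity = 1 − (χ + Δχ) counts independent loops (ball 0, solid
torus 1, two disjoint balls −1); `Conn.D` divides by the physical volume
in µm³.

### Box-counting fractal dimension

The schedule is the geometric sequence from 48 px down to 6 px at factor
1.2, rounded to integers with duplicates removed, grid anchored at the
origin (translation 0); all four constants are exposed in
`BoxCountConfig`.  For each nominal size s, the grid is *fitted to the
image*: an axis of length L is partitioned into `ceil(L/s)` equal boxes
and the occupied-box count is regressed against the effective size
`L/ceil(L/s)`.  This choice eliminates the partial-box artifact of
fixed-size grids on finite images — with overhanging fixed boxes a
filled 128³ volume fits to a slope of ≈ 2.81 rather than 3 — and makes
the filled-volume and one-voxel-plane endpoints exact (3.000 / 2.000).
Schedule entries whose division counts coincide after rounding are
collapsed to one scan.  `fr_dim` is the least-squares slope of
log(count) versus log(1/size); fewer than three distinct scales raises
an error, and an initial box larger than the grid is shrunk to fit and
logged.

Known limitation: on an exactly self-similar set sampled at scales
incommensurate with its similarity ratio, grid counts oscillate above
the power law (lacunarity).  A level-4 Menger sponge (81³) measures
≈ 2.86 under this schedule — exact (20, 400) at the triadic divisions
3 and 9, inflated between them — against the asymptotic
log 20 / log 3 ≈ 2.727.  This is a property of box counting at these
scales, not of the implementation; minimizing counts over grid offsets
does not reduce it (boundary boxes multiply faster than holes empty).

### Skeleton fiber lengths

Connected components smaller than 27 voxels (the noise floor; a 3³
speck) are removed, the volume is thinned to a one-voxel 3D skeleton,
and branches are maximal paths between nodes (end points with one
26-neighbor, junctions with three or more); a node-free cycle counts as
one branch.  Branch length sums the Euclidean step lengths (1, √2, √3
voxels) along the path.  In a dense fiber network the skeleton is
subdivided at every crossing, so the mean *branch* length is much
shorter than the generating fibers; the index is comparative across
regions, not an estimate of true fiber length.

### Grayscale front end

`frangi_tubularity` is the multiscale Hessian vesselness filter
(bright-tube polarity, maximum over scales) and `binarize` applies Otsu
or a fixed threshold, logging the value used.  Both are standard steps
delegated to scikit-image.

## FTIR hyperspectral chain

Spectra live on a strictly descending, uniform wavenumber axis; the
synthesis default is 1800 → 900 cm⁻¹ in 4 cm⁻¹ steps, covering every
analysis band.  The processing order in `region_pipeline` is:
vector normalization → integration maps → HCA → collagen-cluster mean
spectrum → second derivative → Gaussian fits → ratio panel.

- **Normalization**: each pixel spectrum is scaled to unit Euclidean
  norm, removing multiplicative section-thickness variation.  All five
  ratios are invariant under positive scaling, before or after.
- **Integration**: plain trapezoid over the stated window with *no*
  baseline subtraction (a local linear-baseline option exists but is off
  by default).  A window bound falling between axis samples is covered
  by linear interpolation at the bound, so stated windows integrate over
  their exact interval.
- **Atmospheric compensation** is an identity hook with an optional
  region-exclusion list: synthetic spectra contain no atmospheric lines.
- **HCA**: Ward linkage on Euclidean distances between pixel spectra
  (scikit-learn agglomerative clustering).  The cluster count is not
  prescribed by the workflow this mirrors; the default k = 2 reads as
  protein-rich vs collagen-rich, and the collagen cluster is the one
  with the highest mean 1299–1184 cm⁻¹ integral.
- **Second derivative**: Savitzky–Golay, default window 9 points and
  order 3 on the measured grid; band positions are its local minima.
- **Gaussian deconvolution** (lmfit): nonnegative heights, widths
  bounded in [2, 30] cm⁻¹ (so no component swallows its neighbours),
  centroids constrained within ±4 cm⁻¹ of their seeds.  Seeds default to
  second-derivative minima; the pipeline snaps the canonical band list
  (1655, 1550 | 1342, 1319, 1280, 1262, 1240, 1205 cm⁻¹) to detected
  minima within ±4 cm⁻¹, keeping the canonical value when detection
  misses.  An all-zero window returns zero-height components with a
  flag; non-convergence after bounded sigma-perturbed restarts raises a
  fit error with diagnostics.
- **Ratios**: COLL/PRT uses the 1299–1184 window integral by default;
  whether the historical numerator was the window integral or the sum of
  the fitted tricuspid components (1280 + 1240 + 1205) is ambiguous, so
  `collagen_numerator="components"` exposes the alternative.  PRO/PRT,
  TRIPLE HELIX, ALPHA HELIX and RANDOM use the fitted areas of the 1342,
  1280, 1319 and 1262 cm⁻¹ components (matched to the nearest component
  within ±6 cm⁻¹; a missing required band raises an error naming the
  centroid).  The α-helix centroid is quoted variously as 1319 or
  1320 cm⁻¹ in the literature; 1319 is the default and the value is
  configurable.

## Statistics

- `oneway_anova_tukey`: F and p from the standard decomposition, Tukey
  HSD adjusted pairwise p-values from the studentized-range
  distribution (scipy).
- `rm_anova`: one-factor within-subject ANOVA; subjects missing a
  region are dropped with a log line; F = MS_condition/MS_error with
  (k−1), (k−1)(n−1) degrees of freedom.  Verified against both a
  hand decomposition and pingouin.  It reduces to the one-way F when the
  between-subject variance is zero.
- `spearman`: Pearson correlation of mid-ranks (tie handling matters
  because stage takes only four values); p from the t approximation with
  n − 2 df, adequate at the cohort sizes screened here; a seeded
  permutation p-value is available for n ≤ 10.
- `classify_strength`: |ρ| bins [0, .2), [.2, .4), [.4, .6), [.6, .8),
  [.8, 1]; left-closed/right-open with a closed final bin so every value
  has exactly one label (the customary "÷" notation does not fix the
  boundaries; this convention does).
- `correlation_screen`: all pairwise Spearman correlations among the
  requested variables in one region, stage encoded 1–4; significant
  means strong-or-better *and* p < 0.05.  No multiplicity correction by
  default, matching the screening practice it mirrors; Holm adjustment
  is available.

## Synthetic data: what it emulates, and what it does not

- **Fiber phantoms**: straight cylinders spanning the grid, axes drawn
  from a one-knob directional law — `u = normalize(κ·a + ξ)` with ξ
  uniform on the sphere, κ = 0 isotropic, κ → ∞ parallel to the
  principal axis a.  A voxel is foreground when its center lies within
  the fiber radius of an axis.  Fibers are added until the realized
  volume fraction is within 0.02 of target (bounded placements, else a
  convergence error).  Real stroma has curved, tapering, wavy bundles
  and an unknown orientation law; the phantom family is a modeling
  choice for controlled anisotropy sweeps, not a tissue model, so
  passing recovery tests demonstrates estimator correctness, not
  biological fidelity.
- **Geometric phantoms** (filled, plane, ball, torus, two balls, Menger
  sponge, parallel rods, random spheres) carry their analytic quantity
  (volume fraction πr²/pitch², χ, 20^level voxels, fractal dimension)
  computed independently of the estimators.
- **Hyperspectral cubes**: each pixel is the sum of its class's Gaussian
  bands plus optional constant/sloped baseline and i.i.d. noise; the
  default geometry is 64 × 64 pixels at 2.56 µm (4,096 spectra,
  163.84 µm per side) emulating a focal-plane-array map.  The per-class
  analytic ratio panel comes from closed-form (erf) Gaussian areas, no
  noise and no baseline.  Band tables whose ratio-defining bands are
  absent (single-band stress cubes) carry a flagged `None` panel.
  Real tissue spectra add scattering distortions, paraffin residues and
  atmospheric lines, all out of scope here.
- **Cohorts**: one synthetic patient per sample, one record per region
  (IntraT/PeriT/ExtraT) and variable; values are region baselines plus
  planted per-stage shifts, a shared per-patient random effect and
  within-patient noise, both expressed as fractions of the baseline
  (defaults 0.10 / 0.15).  Region baselines follow the expected
  direction (dense, thick, anisotropic collagen in normal stroma; loose
  and sparse in the tumor core).  Cross-variable correlations arise only
  through shared stage effects, which is exactly what the screen's
  recovery tests exploit.

Determinism: every generator and estimator that uses randomness takes a
seed; identical seeds give bit-identical outputs, and the CLI derives
per-stage seeds from one root seed by hashing.

## Problem sizes

Tests and the benchmark script run phantoms at 128³ (anisotropy and
fractal endpoints), 81³ (Menger), 64³ and below (oracle comparisons,
which are brute-force), and hyperspectral cubes at 24–64 pixels per
side; the staged-series recovery uses 25 maps per stage at 24 × 24
pixels with 1% noise.  These sizes keep the full suite around a minute
on one CPU while leaving every estimator's asymptotic regime intact.
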