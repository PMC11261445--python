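# stromakit

Multiscale quantification of stromal collagen: 3D morphometry of
collagen-bundle volumes, FTIR hyperspectral analysis of the same tissue,
and the statistics that link structure, biochemistry and clinical stage.

Fibrous stroma remodels during tumor progression: bundles thin, spread
apart, lose their preferred orientation and their triple-helical order.
Phase-contrast microCT sees the first set of changes (microarchitecture);
infrared imaging sees the second (macromolecular composition).  This
package implements both analysis chains for laboratories working with
such paired data — and, because raw volumes and spectra are rarely
shareable, ships a synthetic-data layer (fiber phantoms, Gaussian-band
hyperspectral cubes, stage-structured cohorts) with closed-form ground
truth so every estimator can be validated end to end.

## What it computes

**3D morphometry** (`stromakit.morphometry`) of a binary volume
`X ⊂ Z³` with isotropic voxel size:

- volume fraction `Vol.% = |X| / |grid|`;
- mean bundle thickness `Th` and spacing `Sp`: the mean over the
  structure (resp. its complement) of the largest-inscribed-sphere
  diameter (local thickness);
- degree of anisotropy from mean intercept lengths: for direction ω,
  `MIL(ω) = (total test-line length) / (phase crossings)`; the point
  cloud `MIL(ω)·ω` is fitted with an ellipsoid and
  `DA = 1 − r_min/r_max ∈ [0 isotropic, 1 parallel]`;
- connectivity density from the Euler characteristic χ of the voxel
  complex: `connectivity = 1 − (χ + Δχ)`, per unit volume (`Conn.D`),
  with Δχ the mirror-tile correction for structure cut by the border;
- box-counting fractal dimension: slope of `log N(s)` vs `log(1/s)`
  over a geometric box-size schedule (48 px → 6 px, factor 1.2);
  2 for a plane, 3 for a space-filling structure;
- mean fiber length from branch lengths of the 3D medial-axis skeleton.

**FTIR imaging** (`stromakit.ftir`): per-pixel vector normalization;
band-integration maps over 1720–1470 cm⁻¹ (amide I+II, total proteins)
and 1299–1184 cm⁻¹ (amide III, collagen); Ward/Euclidean hierarchical
clustering to isolate collagen-rich pixels; Savitzky–Golay second
derivative for band localisation; Gaussian deconvolution; and five
ratios: COLL/PRT, PRO/PRT (1342 cm⁻¹ proline), TRIPLE HELIX
(1280 cm⁻¹), ALPHA HELIX (1319 cm⁻¹), RANDOM (1262 cm⁻¹) — the last
three as fractions of the 1360–1184 cm⁻¹ area.

**Statistics** (`stromakit.stats`): one-way ANOVA + Tukey HSD,
one-factor repeated-measures ANOVA across the three stromal regions
(IntraT / PeriT / ExtraT), tie-aware Spearman rank correlation, and a
screen that labels |ρ| in 0.2-wide bands (very weak … very strong) and
flags pairs with |ρ| ≥ 0.6 and p < 0.05.

## Worked example

```python
import numpy as np
from stromakit import synthetic, morphometry, ftir

spec = synthetic.FiberPhantomSpec(
    grid_shape=(64, 64, 64), voxel_size_um=1.0, fiber_radius_um=3.0,
    target_volume_fraction=0.25, orientation_concentration=4.0, seed=42,
)
vol, truth = synthetic.make_fiber_phantom(spec)
summary = morphometry.morphometry_summary(vol, n_directions=128, seed=1)
```

prints (via `summary.as_dict()`):

```
volume fraction   0.230  (generator truth 0.230)
thickness (um)    5.72
spacing (um)      16.88
anisotropy DA     0.679
fractal dim       2.740
conn. density     1.54e-04 per um^3
mean fiber length 2.3 um
```

The volume fraction matches the generator's brute-force voxel count
exactly; thickness ≈ 5.7 µm is the fiber diameter (2 × 3 µm) minus the
discretization of thin overlapping rods; `DA = 0.68` reflects the
partially aligned orientation law (`concentration = 4`); the fractal
dimension sits between plane-like (2) and space-filling (3); the short
mean branch length is characteristic of a densely connected network,
whose skeleton is subdivided at every fiber crossing.

The spectral side, on a noisy two-class cube with known band areas:

```python
cube, cube_truth = synthetic.make_two_class_cube((32, 32), noise_sd=0.01, seed=7)
result = ftir.region_pipeline(cube)     # normalize -> maps -> HCA -> fit -> ratios
print(result.panel.as_dict())
```

```
coll_prt     0.3010  (analytic truth 0.3011)
pro_prt      0.0822  (analytic truth 0.0822)
triple_helix 0.2147  (analytic truth 0.2125)
alpha_helix  0.1518  (analytic truth 0.1518)
random_coil  0.1074  (analytic truth 0.1093)
```

Every ratio lands within ~2% of the closed-form Gaussian-area quotient
planted by the generator.

A command-line surface wraps the same layers
(`stromakit simulate | morpho | ftir | stats | pipeline`); re-running
`stromakit pipeline --seed 7` reproduces byte-identical reports.

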