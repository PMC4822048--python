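# Methods

## The heterogeneity model

The package treats a tumor as the set of `M` voxels of a segmented region
of interest over a 3D SUV grid.  Heterogeneity is measured locally — as
absolute SUV differences between 26-connected neighbor pairs inside the
mask — and aggregated globally with a radial weight:

    |H| = (1/M) Σ_{i=1..M} (d_i / d_max) · (1/N_i) Σ_{j=1..N_i} |ΔSUV|_ij / SUV_th

* `N_i` is the number of in-mask neighbors of voxel `i` (0–26).  Voxels
  with `N_i = 0` (isolated mask islands) contribute nothing.
* `d_i` is the Euclidean distance from voxel `i` to the SUV-weighted
  centroid `r_c = Σ SUV_i x_i / Σ SUV_i`, by default in physical mm
  (an index-space option exists for isotropic phantom work; the weight is
  a ratio, so on isotropic grids the two coincide).
* Division by `SUV_th` makes H dimensionless; the `1/N_i` and `1/M`
  normalizations keep H from growing trivially with tumor size, so the
  "size weighting" is carried entirely by `d_i/d_max`.
* A single-voxel tumor has H = 0 by convention (no neighbor differences
  and no distance scale), not an error.

**Sign.**  The inner core is `{i : d_i ≤ f·d_max}` with `f = 0.5` — a
radial shrink of the tumor toward its center by half.  If the whole-tumor
mean SUV is less than or equal to the inner-core mean, the uptake descends
from center to periphery and H gets a `+`; otherwise `−`.  Ties take the
descending branch.  "Shrunk by 1/2" admits other readings (half volume,
half linear extent); the radial-fraction reading is the simplest
consistent one and `f` is configurable (`HConfig.inner_fraction`).

**Assumptions.**  Inputs are already SUV-calibrated (g/ml); adjacency is
26-connectivity in index space regardless of anisotropic spacing (the
neighbor *count* convention is fixed at 26/8, while *distances* do honor
spacing); a single connected lesion is analyzed at a time (an optional
largest-component filter handles multifocal thresholding).

## Parameters that matter

| parameter | unit | default | role |
|---|---|---|---|
| `suv_th` | g/ml | 2.5 | segmentation cutoff (inclusive, `SUV ≥ suv_th`) and H normalizer |
| `inner_fraction` | — | 0.5 | radial extent of the inner core for the sign rule |
| `use_physical_spacing` | — | true | centroid distances in mm vs voxel index units |
| `glcm n_levels` (G) | — | 64 | gray levels for SUV quantization |
| `entropy_base` | — | e | natural log (nats); base 2 optional |

The inclusive threshold is a deliberate choice: a tumor whose minimum
uptake equals the cutoff is kept intact; whether clinical workstations
use ≥ or > at the boundary varies and is not knowable from outside.

## GLCM conventions

SUV is quantized to `G` equal-width bins spanning the in-mask min–max
range (the dominant radiomics convention; the top bin is right-closed so
the maximum maps to level G, and a constant region maps to level 1).  The
co-occurrence matrix pools *all* nearest-neighbor displacements at d = 1
— every offset and its negation — counting only ordered pairs with both
endpoints in the mask, which makes P symmetric by construction and
restricts texture to the tumor.  `total_pairs = Σ_i N_i` and is even.
Energy, Contrast, Local Homogeneity and Entropy follow the standard
Haralick forms (`Σp²`, `Σ(g−h)²p`, `Σp/(1+(g−h)²)`, `−Σp·log p` with
0·log 0 = 0).  Because the quantization used for published patient
analyses is generally unstated, comparisons against external feature
values should be made on orderings and correlations, not raw magnitudes.

## Digital phantoms

The validation inputs are generated, not stored.  The 3D family is a
sphere of radius `r_max = 30` voxels with a *modified Gaussian* radial
profile `SUV(d) = B + A·exp(−d²/R²)`, A and B solved so the center reads
40 g/ml and the surface 2.0; `R = 0` degenerates to the homogeneous
baseline (constant 2.0).  This offset-Gaussian is the minimal form
satisfying both boundary pins and lives in one function
(`gaussian_sphere_profile`) so an alternative profile is a one-line swap.
Sub-spheres of radius `r_s` at distance `D` from the host center (host
`R = 30`) model peripheral high-uptake niduses: each follows its own
modified Gaussian from 40 at its center down to the host's SUV at its
boundary.  Two choices here were genuinely open and are made once:

* the sub-sphere Gaussian width is `R_s = r_s` (the profile scales with
  the sphere), and
* its surface value is matched *per direction* — the host profile is
  evaluated analytically at the boundary point along each voxel's radial
  ray — so the assembly is continuous at the `r_s` surface.
* placement for `N = 1..4` sub-spheres is deterministic: `+x, −x, +y, −y`
  at distance `D`, maximally separated in the central plane.  Overlapping
  sub-spheres or spheres leaving the host/grid are errors.

Background voxels (outside the host sphere) default to 0 so threshold
segmentation at 2.5 recovers a sphere-interior mask; phantom sweeps use
the geometric sphere mask directly, since the analytic lesion is the ROI
by construction and the homogeneous baseline (2.0 everywhere) would
otherwise segment empty.

The 2D family is six deterministic 32×32 single-slice patterns: two
equal-mean (exactly 5) images of very different roughness (smooth halves
vs a 1/9 checkerboard), a center-peaked radial profile, quadrants, a
linear ramp, and a center-cold parabola whose ascending profile produces
a negative H.  They are parameterized analogs constrained by documented
properties, not reproductions of any particular published pixel pattern.

**What the phantoms do not emulate:** PET acquisition physics — Poisson
count noise, reconstruction point-spread blur, partial-volume effects,
respiratory motion — and realistic lesion shapes.  Tests passing on these
phantoms validate the *mathematics* of the index (orderings, invariances,
exact small-case values), not its robustness to scanner noise or its
clinical effect sizes.

## Numerical choices

* Voxel index `k` sits at physical position `k × spacing`; only relative
  distances are observable, so the origin convention is cosmetic.
* `d_max = 0` (single voxel) defines all weights as 0.
* The centroid requires at least one positive in-mask SUV; an all-zero
  mask is an error rather than a silent 0.
* The vectorized neighbor accumulation (26 shifted-slice passes) is
  checked against plain triple-loop references to 1e−10 relative (H) and
  exactly (co-occurrence counts) on random grids.
* Feature CSVs are written with `%.17g` so doubles round-trip
  (`pd.read_csv(..., float_precision="round_trip")`).

## Problem sizes

The benchmark sweep runs on an 80³ grid (sphere interior ≈ 113 k voxels,
13 phantoms, a few seconds total); cross-check oracles run on random
grids up to 8³ where exhaustive enumeration is exact and fast; invariance
checks use 48³ spheres (`r_max = 20`).  These sizes were chosen so the
full validation suite runs comfortably on a laptop while every assertion
remains at full numerical strength.

## Known limitations

* H depends on the segmentation: the threshold enters both the mask and
  the normalization, so indices computed at different `SUV_th` are not
  directly comparable.
* The 26-neighbor convention ignores anisotropic spacing in *adjacency*
  (a design choice keeping `N_i ≤ 26` exact); strongly anisotropic voxels
  make "neighbors" physically asymmetric.
* GLCM features depend on `G` and the binning range; only the constant
  image has quantization-free values.
* No patient data ships with the package; the correlation utility
  (`correlate`) is generic and expects user-supplied feature/outcome
  tables with ≥ 3 paired observations.
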