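# Methods

## Problem and model

The package quantifies whether epicardial adipose tissue (EAT) spatially
colocalizes with left-atrial (LA) wall fibrosis. The analysis objects are a
triangulated LA endocardial surface S (vertices x_i in world mm), a set of
volumetric fat samples {(p_j, v_j)} with positions p_j (mm) and volume
weights v_j (mm³), and a per-vertex binary fibrosis label. Two metrics are
computed per vertex:

* **EAT proximity**: d_EAT(x) = min_j ‖x − p_j‖, the Euclidean distance to
  the nearest point of the fat volume;
* **local EAT volume**: V_EAT(x) = Σ_{j : ‖x − p_j‖ ≤ r} v_j, with r = 5 mm
  (closed ball; boundary samples count);
* derived **coverage**: 1{V_EAT(x) > 0} = 1{d_EAT(x) ≤ r}.

Vertex values are stratified by fibrosis label and compared with the
two-sided Mann–Whitney U test; groups are summarised by median and IQR
(quartiles by linear interpolation of order statistics).

"Nearest point within the fat volume" is implemented as nearest volumetric
*sample point*: fat voxels are subdivided so sample spacing ≤ 1 mm, hence
this differs from the distance to the fat boundary by at most half the
sample spacing — below image resolution. Similarly "every point on the LA
surface" means every mesh vertex; vertex density is set by voxel size.

## Pipeline stages and defaults

| parameter | default | meaning |
|---|---|---|
| `dilation_mm` | 2 | metric wall thickness: wall = dilate(endo, ball(2 mm)) − endo |
| `threshold_k` | 3 | fibrosis threshold μ + k·σ over wall LGE intensities |
| `fat_sample_spacing_mm` | 1 | max spacing of volumetric fat samples |
| `radius_mm` | 5 | V_EAT / coverage query radius |
| `max_assign_mm` | 3 | max vertex-to-wall distance for label transfer |
| `aggregation` | pooled | vertex-level pooling across cases (`per_case` optional) |
| `height_cm`, `weight_kg` | 179, 90.7 | BSA inputs for volume indexing |

**Wall and fibrosis.** The dilation ball is metric (built from voxel
spacing, so anisotropic grids are handled) and clipped at the grid edge.
The threshold reference (μ, σ) is estimated by iterative 3σ clipping: start
from the median and 1.4826·MAD of all wall intensities, exclude voxels above
μ + 3σ, re-estimate, repeat to a fixed point. A single-pass median/MAD is
already visibly biased when ~30 % of the wall is enhanced (the enhanced mode
drags both statistics and pushes the threshold into the enhanced
distribution); the clipped estimate stays anchored to the normal-wall mode
while remaining scale-equivariant (rescaling all intensities by c > 0 leaves
the fibrotic mask unchanged). The clip level is fixed at 3σ regardless of
`threshold_k`, so a pathological detection threshold (e.g. very negative k)
cannot destroy the reference estimate. The exact rule used by the commercial
service in the source methodology is unpublished; k and the reference choice
are therefore configuration, and no result here depends on a specific k
reproducing a clinical value.

**Surface extraction.** Marching cubes at level 0.5 of the binary field,
vertices in world mm, followed by 10 iterations of shrink-compensated Taubin
smoothing (λ = 0.5, ν = 0.53). The raw marching-cubes surface of a binary
field carries a staircase area bias of roughly +9 % that does not vanish
with resolution; Taubin relaxation removes it while changing enclosed volume
by < 1.5 % on analytic test spheres. `smoothing_iterations=0` restores the
raw surface for auditing. Masks touching the grid boundary are rejected
(the surface would be clipped open) rather than silently padded.

**Label transfer.** Each vertex takes the fibrosis label of the nearest
wall-voxel centroid (deterministic; exact ties broken toward the lowest
linear voxel index). Vertices farther than `max_assign_mm` from any wall
voxel are labeled non-fibrotic and counted in a warning. Nearest-neighbour
transfer was chosen over normal-ray casting for determinism and simplicity;
on closed, smooth phantoms the two agree except at patch boundaries.

**Fat volumetrization.** Each fat voxel is split into ceil(spacing/target)
sub-cells per axis; each sample carries its sub-cell volume, so the total is
exactly voxel count × voxel volume (conserved to 1e-9 relative under any
subdivision). A tetrahedral mesh is deliberately not used: the metrics
consume only point positions and volume weights, and ≤ 1 mm sample spacing
reproduces the effective resolution of a ~1 mm tetrahedralization.

**Registration.** Frames are aligned by the closed-form least-squares rigid
fit (cross-covariance SVD with reflection correction) on ≥ 3 non-collinear
named landmarks — the same degrees of freedom (rotation + translation, no
scaling) as manual alignment, but deterministic and testable. The fit is
provably optimal in the least-squares sense; tests verify noiseless recovery
to < 1e-6 mm RMS and superiority over 1,000 random rigid motions under
0.5 mm landmark noise.

**Spatial queries.** Both metrics use a k-d tree, but the tree only supplies
candidate indices: distances are recomputed from coordinates and ball sums
run over ascending sample indices, so results are *bit-identical* to the
exhaustive O(N·K) scan (asserted, not approximately, in tests).

**Statistics.** U is computed from mid-rank sums. For tie-free problems with
n_a + n_b ≤ 20 the two-sided p comes from full enumeration of the null rank
distribution (dynamic programming over subset sums); otherwise the normal
approximation with tie-corrected variance and 0.5 continuity correction is
used. The two branches agree to within 0.01 at n = 10 + 10, and the exact
branch matches an independent enumeration oracle. Cohort aggregation pools
vertex-level values across cases by default; this treats vertices as
observations and inflates effective n, so group sizes are always reported
and a `per_case` mode (median per case, then test across cases) is provided
as the conservative alternative. BSA for volume indexing uses Mosteller
(√(height·weight/3600)); DuBois is available via `bsa_formula="dubois"`.

## Synthetic phantom

The generator emulates the structures the analysis needs, not MRI physics:

* LA blood pool: ellipsoid, default semi-axes 24 × 20 × 18 mm, centred in a
  96³ grid at 1 mm isotropic spacing (cohort tests use 72³ at 1.25 mm).
* Wall: metric dilation of the voxelized pool by `wall_thickness_mm` (2 mm)
  minus the pool — the *same operation* the pipeline applies, so planted
  enhancement and re-derived wall coincide voxel for voxel.
* Pericardial shell: ellipsoidal shell at a 6 mm outward gap, 1.5 mm thick.
* Fat: 10 spherical depots of radius 6 mm centred on the mid-gap surface,
  strictly clipped to the layer between wall exterior and pericardium. The
  defaults give ~5–6 mL of LA fat and ~40 % non-fibrotic surface coverage at
  5 mm — a contiguous-depot geometry of plausible scale, though below the
  clinical LA-fat volume, which wraps the atrium far more extensively than
  discrete depots. A separately labeled fat slab low in the grid stands in
  for ventricular fat so total-vs-LA fat indexing is exercised.
* Fibrosis: angular caps on the wall (contiguous patches, as in clinical LGE
  maps, not voxel speckle). Cap angular radius is solved by bisection on the
  actual wall voxels so the achieved fibrotic fraction matches the request
  (default 0.17, the scale of reported clinical medians) to ±0.03.
* LGE signal: Gaussian baseline (mean 40, SD 5, arbitrary units) with
  fibrotic wall voxels shifted by +30 (i.e. +6 SD). Additive Gaussian noise
  is the simplest model that exercises thresholding; no Rician noise, bias
  fields or partial-volume effects.
* Frames: landmarks (two pulmonary-vein analogs, mitral-annulus analog,
  appendage analog) are generated in the canonical frame and mapped by a
  known rigid transform (default 5°/−3°/8° rotations, (4, −2, 3) mm
  translation) to the fat frame; the pipeline carries the fat model into
  that frame and registers it back.
* `coloc_mode`: `near` draws depot directions inside the fibrotic caps,
  `far` rejects directions within (cap radius + 0.35 rad) of any cap centre,
  `random` is uniform. This is the ground truth the direction-recovery
  tests assert against.

Cohorts derive per-case seeds from a master seed via `SeedSequence`, so a
cohort is reproducible and cases are independent; identical config + seed
gives bit-identical volumes.

### What the phantom does and does not show

Passing tests demonstrate that the *measurement chain* is correct: metric
wall construction, unbiased threshold recovery of planted enhancement at
+6 SD contrast, geometrically faithful surfaces, exact spatial queries,
optimal rigid alignment, and recovery of a known colocalization direction
with the stated test. They do not validate performance on clinical images —
no intensity inhomogeneity, motion, partial volume, anisotropic clinical
voxels (beyond what tests exercise), manual-contouring variability, or
realistic LA/fat morphology. Clinical-cohort statistics (regressions,
correlations with BMI, reliability coefficients) are out of scope.

## Numerical choices and degenerate inputs

* All geometry is computed in world mm via an axis-aligned affine (voxel
  centre at index·spacing + origin); raw index arithmetic never carries a
  metric meaning.
* Ball inclusion for V_EAT is closed (≤ r); ties at exactly r are included.
* Empty fat: d_EAT is an error ("no EAT present" — a minimum over an empty
  set), while V_EAT is a valid all-zero map; an empty fat mask volumetrizes
  to a valid empty model with total volume 0.
* Empty stratification groups are flagged, never silently dropped;
  comparisons refuse flagged input.
* Zero intensity spread in the wall with k > 0 returns 0 % with a warning;
  NaN intensities are an error.
* Degenerate landmark configurations (< 3 points, collinear, mismatched
  names) are rejected before fitting.
* p-values are clamped to the smallest positive normal double rather than
  underflowing to 0 (pooled vertex counts make astronomically small p
  routine; the clamp keeps "p > 0" invariants honest).

## Problem sizes

Default test and acceptance runs use 72³–116³ grids at 0.5–1.25 mm spacing,
cohorts of 10 cases, and oracle comparisons up to 2,000 vertices × 5,000 fat
samples — sizes chosen so the full chain (including brute-force oracles)
completes in seconds per case while keeping ≥ 30 mesh vertices per fibrotic
patch and sub-voxel geometric tolerances meaningful.
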