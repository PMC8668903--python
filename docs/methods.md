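# Methods

`sbfquant` quantifies the 3D bioarchitecture of tumour tissue from serial
block-face electron-microscopy (SBF-SEM) label volumes. This note describes
the models and procedures each stage implements, the parameters that matter,
what the synthetic scene generator does and does not emulate, and the
numerical conventions.

## Coordinate and unit conventions

Volumes are arrays indexed `[ix, iy, iz]` (shape `(nx, ny, nz)`), `iz` along
the sectioning axis. Voxel spacing `(dx, dy, dz)` is given in nanometres and
is typically strongly anisotropic (block-face imaging resolves ~15 nm
laterally but sections at ~100 nm). A voxel's physical position is its
**centre**, `((ix+0.5)dx, (iy+0.5)dy, (iz+0.5)dz)`; centre-based positions
make centroids and distances unbiased. Positions and distances are reported
in µm, volumes in µm³. Spacing is never read from TIFF metadata (dialects
are unreliable); it is explicit input everywhere.

Labels are stored as one integer volume plus a segment table (id → class,
parent), mirroring how annotation tools export nested structures: a cell's
voxels are split between its own id (cytoplasm) and the ids of its nucleus
and mitochondria, and whole-cell measurements aggregate the family.

## Pre-processing

Sections are cropped to a rectangular field of view and normalized strictly
per section: z-score against the section's own mean and population standard
deviation, clip at ±`clip_sigmas` (default 3), map affinely to [0, 255] and
round (ties away from zero). Per-section normalization removes
section-to-section brightness drift; the 3σ clip bounds the influence of hot
pixels. A constant section maps to mid-grey (128) with a warning. The
32-bit → 8-bit transfer function is not standardised by any acquisition
convention; the clipped-z map is this package's choice and is monotone
within each section.

## Flow-based label propagation

Manual segmentation of hundreds of cells over hundreds of sections is the
bottleneck of volume EM, so annotations are drawn on only one section out of
`stride` (default 10) and propagated. The displacement field between
neighbouring sections is estimated with coarse-to-fine variational TV-L1
optical flow (quadratic coupling + total-variation smoothness, median
prefiltering of the warped image; `smoothness_weight` is the coupling weight,
default 15; 5 warping iterations). Labels are categorical, so warping is
nearest-neighbour: `out(p) = labels(p − u(p))`, out-of-bounds → background.

Each unannotated section receives the labels of its **nearest annotated
section** (ties to the lower index, for determinism), warped through the
chain of section-to-section flows rather than by one long-range flow — EM
content decorrelates within a micrometre along z, so adjacent-pair flows are
the only reliable ones. Propagation is single-source; bidirectional blending
from both flanking annotated sections was considered and rejected because
blending two categorical label fields needs an arbitration rule that is hard
to make deterministic and adds little on the ≤ stride/2 chains used here.
Propagation can only move labels, never create ids.

On translating-object phantoms (≤2 px/section, stride 10) the mean
per-section intersection-over-union against ground truth exceeds 0.85; a
static stack is reproduced exactly (the flow chain is identically zero).

## Morphometry

Volume = voxel count × voxel volume; centroid = mean of voxel centres.
A structure is **complete** when none of its voxels lies on any of the six
stack faces — the simplest testable notion of "entirely contained".
Cytoplasm is derived as cell minus nucleus rather than segmented
independently (the published volumetry of a fully segmented hepatoblastoma
cell — cell 970.6, cytoplasm 657.1, nucleus 313.6 µm³ — is consistent with
this convention to 0.1 µm³). Mitochondria belong to the cytoplasmic
compartment. The nucleocytoplasmic ratio is nucleus/cytoplasm. Analyses
keep cells with a complete nucleus; the stricter filter (cell body complete
as well) is used where whole-cell volumes matter. Completeness of the
mitochondrial network is not required — mitochondria are numerous (hundreds
per cell) and individually tiny, so a clipped mitochondrion perturbs volumes
negligibly while the criterion would discard most cells.

## Orientation analysis

A structure's **main axis** is the leading eigenvector of the covariance of
its voxel-centre coordinates in physical units (PCA). Axes are unsigned;
the sign is canonicalised (first nonzero component positive). A near-tie
λ1 ≈ λ2 flags the axis as ambiguous and excludes the cell from ray casting.

The **alignment plane** of a bundle of axes minimises Σᵢ (n·aᵢ)² = Σᵢ sin²θᵢ
over unit normals n — axial least squares, solved exactly by the smallest
eigenvector of the scatter matrix Σ aᵢaᵢᵀ. The fit is unweighted: with no
principled size or elongation weighting to prefer, every complete-nucleus
cell counts equally. Capillary and nucleus axes are scored against the
cells' plane but never enter the fit. Inclination = arcsin|n·a| ∈ [0°, 90°];
histograms use 10° bins (last bin closed at 90°) and the 0–20° share counts
20° inclusively.

## Polarity (virtual rays)

Every cell emits a ray: the infinite line through its centroid along ± its
main axis, clipped to the volume. A voxel at perpendicular distance d from
the line receives intensity `falloff(d)`; the default profile is linear,
1 on the axis and 0 at the ray radius, and the profile is pluggable. Each
cell contributes at most its single footprint value per voxel, so the
accumulated map reads as a weighted count of converging cells and the
threshold τ (default 3.5 a.u.) means "more than 3.5 cells' worth" of
convergence. The **hot spot** is the largest 26-connected component of
voxels strictly above τ; a cell is **polarized** when its ray deposits
nonzero intensity inside the hot spot. Rays have no length cap.

The ray radius must be matched to the field of view and the expected
aiming spread. Two constraints bound it: for recall, the tube must be wider
than the typical miss distance of a convergent cell, ≈ d·sin σ for a cell at
distance d from the convergence point with angular spread σ; for precision,
the background accumulation of non-convergent rays, ≈ n_cells · (πr²L/V) ·
mean falloff, must stay well below τ. At the reference radius of 15 µm in a
~70 µm field both hold for real-scale stacks; on the desk-scale synthetic
grid (38.4 × 38.4 × 19.2 µm) they give r ≈ 2.5 µm, which the test scenes
use. With 40 cells of which 15 aim at a common point with σ = 5°, the
aimed subset is recovered with precision and recall ≈ 0.85 and the hot-spot
centroid localises within 2r of the true convergence point.

## Distances and statistics

Distance to the capillary is the exact anisotropic Euclidean distance
transform of the capillary mask (voxel-centre to voxel-centre, µm). The
primary per-structure distance is the minimum over the structure's voxels
(surface-to-surface proximity); the distance interpolated at the centroid
is kept as a secondary column since minima over large structures are
size-dependent by construction.

Monotone associations use Spearman's rank correlation with mid-ranks for
ties. The two-sided p-value is exact (full permutation enumeration) for
n ≤ 9 and the t-approximation `t = ρ√((n−2)/(1−ρ²))`, df = n−2, otherwise;
the exact null of ρ at n = 21 (21! orderings) is not enumerable, and the
t-approximation differs slightly from other software's conventions at small
n. Significance is p < 0.05 with no multiple-testing correction, matching
standard practice for this analysis. At n = 21 the empirical type-I error
of this rule is within [0.03, 0.07] and the power against a Gaussian-copula
alternative with population ρ_s = −0.6 is ≈ 0.82.

## Synthetic scenes

The generator provides the ground truth that the real acquisitions cannot:
per-cell centres, semi-axes, axes, convergence membership and capillary
distances.

* **Cells** are triaxial ellipsoids, prolate with aspect ratio drawn from
  [1.5, 3] so the major axis is analytically the PCA axis — orientation
  estimates have exact oracles. Major radius ~ N(3.5, 0.6²) µm on the desk
  grid (clipped to [0.4, 2]× the mean).
* **Placement** is sequential rejection sampling (default 1000 attempts per
  cell) with a support-function separation test along the centre line plus a
  one-voxel margin — sufficient for disjointness and much tighter than
  bounding spheres. Cells may protrude through the stack faces and are then
  marked incomplete in the truth; `contain_cells=True` restricts centres so
  every cell is fully contained (used by recovery experiments that need all
  axes unbiased by clipping).
* **Nuclei** are concentric scaled copies (volume fraction 0.32, the
  published nucleus/cell ratio 313.6/970.6); **mitochondria** are small
  spheres (0.25 µm radius) in the cytoplasmic shell, with per-cell counts
  drawn from the configured range and scaled by relative cell volume so
  mitochondrial load tracks cell size, as observed in tissue. The desk
  default range 20–40 per cell keeps label counts tractable (real cells
  carry 200–400).
* **Orientation models**: isotropic; plane-aligned (uniform in-plane
  direction tilted out of plane by a wrapped-normal angle, σ in degrees);
  hotspot (a fixed fraction of cells aim at a common point with
  wrapped-normal angular error). At σ ≈ 17° the expected share of
  inclinations ≤ 20° is 2Φ(20/17) − 1 ≈ 0.76.
* **Capillary**: a straight cylinder; cells keep clear of it. An optional
  slope couples mean cell radius to capillary distance (negative volume-
  distance correlation when positive).
* **Rendering** produces an EM-like stack: per-class base grey levels, a
  smooth within-cell texture field, Gaussian noise, and optional per-section
  integer jitter (recorded in the truth) to exercise flow estimation.

The phantom is geometric only: no membranes, stain physics, charging
artefacts, organelle ultrastructure, cell crowding/deformation, or
non-convex shapes. Tests passing on these scenes demonstrate that the
estimators recover known parameters under realistic sampling anisotropy and
noise — not that segmentation of real EM contrast is solved (the package
consumes segmentations; it does not produce them from raw images beyond
flow propagation of sparse annotations).

## Problem sizes

The default test grid is 256 × 256 × 64 voxels at 150 × 150 × 300 nm
(38.4 × 38.4 × 19.2 µm): all physical formulas are scale-free, and this
size exercises the full pipeline — including 20-seed recovery experiments —
in minutes on a single core. Full-resolution acquisitions (~4700² px ×
250 sections) differ only in memory and time, not in code paths;
`propagate_stack` and `accumulation_map` stream one section / one cell at a
time for that reason.

## Known limitations

* Flow propagation assumes in-plane motion between sections; structures
  appearing/disappearing mid-interval (caps of cells) are filled from the
  nearest annotated section and can inherit its topology.
* The alignment-plane fit assumes a single dominant plane; bimodal axis
  distributions yield a compromise normal (flagged only via the objective).
* `classify_polarized` counts any ray touching the hot spot; it does not
  rank cells by deposited intensity.
* The t-approximation p-value is approximate for 9 < n ≲ 15; the exact
  branch covers smaller samples.
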