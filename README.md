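# sbfquant

Quantitative 3D bioarchitecture of tumour tissue from serial block-face
electron microscopy (SBF-SEM) label volumes.

Volume EM produces aligned stacks of sections with nanometre lateral
resolution over tissue blocks containing hundreds of cells. Given such a
stack and (sparse) structure segmentations — tumour cells, nuclei,
mitochondria, a blood capillary — this package answers the architectural
questions a tissue biologist asks of the reconstruction:

* **How big is everything?** Volumes, centroids and completeness of every
  labelled structure; per-cell composition (cytoplasm = cell − nucleus,
  mitochondrial load, nucleocytoplasmic ratio).
* **Are the cells aligned?** Each structure's main axis is the leading
  principal component of its voxel coordinates in physical units; the best
  **alignment plane** of a bundle of unsigned axes minimises
  Σᵢ (n·aᵢ)² = Σᵢ sin²θᵢ (solved exactly by eigen-decomposition), and
  inclination angles θ = arcsin|n·a| are histogrammed in 10° bins.
* **Do cells point at something?** Every cell emits a virtual ray along ±
  its main axis with radial intensity 1 − d/r; voxel-wise accumulation
  across cells yields a convergence map, the largest 26-connected region
  above a threshold (default 3.5 a.u.) is the **hot spot**, and cells whose
  rays reach it are **polarized**.
* **Does the vasculature matter?** Exact anisotropic Euclidean distance
  transform to the capillary; Spearman rank correlations (mid-ranks; exact
  permutation p for n ≤ 9, t-approximation otherwise, significant at
  p < 0.05) between component volumes and capillary distance.

Because manual dense annotation is the bottleneck, the package includes
semi-automatic **label propagation**: annotate 1 section in 10, estimate
TV-L1 optical flow between neighbouring sections, and warp the nearest
annotated section's labels through the flow chain.

A first-class **synthetic scene generator** stands in for raw acquisitions:
ellipsoidal cells with nuclei and mitochondria, a cylindrical capillary,
plane-aligned or hotspot-convergent axis distributions, a cell-size gradient
with capillary distance, EM-like rendering with noise and per-section
jitter — all with exact per-cell ground truth, so every estimator is tested
for parameter *recovery*, not just self-consistency.

## Worked example

Generate a convergent scene, recover the polarized subset, and correlate
cell size with capillary distance:

```python
import numpy as np
import sbfquant as sq

# 40 ellipsoidal tumour cells; 15 aim their major axis at a common point
cfg = sq.SceneConfig(
    n_cells=40, seed=2, mito_per_cell=(0, 0),
    orientation_model=sq.Hotspot(point_um=(19.2, 19.2, 9.6),
                                 fraction=15 / 40, sigma_deg=5),
)
scene = sq.generate_scene(cfg)

axes = sq.axes_from_labels(scene.labels, scene.segments, "cell")
res = sq.run_polarity(axes, scene.labels.dims, scene.labels.spacing,
                      sq.RayParams(radius_um=2.5, threshold=3.5))
truth = set(scene.truth.cells[scene.truth.cells.polarized].cell_id)
tp = len(res.polarized_ids & truth)
print(f"polarized: {len(res.polarized_ids)} cells, "
      f"precision {tp / len(res.polarized_ids):.2f}, recall {tp / len(truth):.2f}")
print(f"hot spot: {int(res.hotspot_mask.sum())} voxels, "
      f"peak accumulation {res.accumulation.max():.1f} a.u.")
```

```
polarized: 15 cells, precision 1.00, recall 1.00
hot spot: 8338 voxels, peak accumulation 8.5 a.u.
```

The classifier recovered exactly the 15 truly aimed cells: their rays stack
up to a peak of ~8.5 overlapping-ray units at the convergence point, far
above the 3.5 threshold, while the 25 isotropic bystanders never push the
background accumulation near it.

Orientation analysis reads the same way on a plane-aligned scene:

```python
cfg = sq.SceneConfig(n_cells=50, seed=1003, mito_per_cell=(0, 0),
                     contain_cells=True,
                     orientation_model=sq.PlaneAligned(normal=(0, 0, 1),
                                                       sigma_deg=17))
scene = sq.generate_scene(cfg)
meas = sq.measure_all(scene.labels, scene.segments)
kept = sq.select_complete(meas, scene.segments, mode="nucleus_only")
axes = sq.axes_from_labels(scene.labels, scene.segments, "cell",
                           ids=[int(i) for i in kept.label_id])
plane = sq.fit_alignment_plane(axes)
hist = sq.angle_histogram(list(plane.inclinations_deg.values()))
print(f"n={hist.n} cells, share of inclinations 0-20 deg: {hist.share_0_20:.1%}")
```

```
n=50 cells, share of inclinations 0-20 deg: 64.0%
```

With a 17° angular spread the expected share at ≤20° is 2Φ(20/17) − 1 ≈ 76%;
a single 50-cell sample scatters around that with a binomial sd of ~6
points (this seed draws low). `scripts/acceptance.py` pools several scenes
to estimate the share tightly.

A command-line pipeline mirrors the library
(`sbfquant simulate / preprocess / propagate / measure / orient / polarity /
report`), exchanging multi-page TIFFs, CSV tables and JSON manifests.

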