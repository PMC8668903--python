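"""Virtual-ray convergence analysis of cell orientation (polarity).

Every cell emits a virtual ray: the infinite line through its centroid along
its main axis, in both directions, clipped to the volume.  The ray deposits
intensity in every voxel whose centre lies within a perpendicular physical
distance ``d <= radius`` of the line, with a radial falloff profile equal to
1 on the axis and 0 at the radius (linear by default).  Summing the
per-cell footprints voxel by voxel yields an accumulation map whose value
reads as a weighted count of converging cells; the largest 26-connected
component above a threshold is the convergence *hot spot*, and a cell is
*polarized* when its ray reaches the hot spot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .orientation import PrincipalAxis
from .volume_model import VoxelSpacing


def linear_falloff(d_um: np.ndarray, radius_um: float) -> np.ndarray:
    """Default radial profile: 1 on the axis, linear decay to 0 at the radius."""
    return np.clip(1.0 - d_um / radius_um, 0.0, None)


@dataclass(frozen=True)
class RayParams:
    """Ray radius (µm), hot-spot threshold (a.u.) and radial falloff.

    The default 15 µm radius and the ``> 3.5`` accumulated-intensity
    threshold suit stacks tens of µm across; the radius should scale with
    the field of view (see the methods note).  ``falloff(d, radius)`` must be
    1 at d=0 and 0 for d >= radius.
    """

    radius_um: float = 15.0
    threshold: float = 3.5
    falloff: Callable[[np.ndarray, float], np.ndarray] = linear_falloff

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError("radius_um must be > 0")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")


@dataclass
class PolarityResult:
    accumulation: np.ndarray  # float32 grid, a.u.
    hotspot_mask: np.ndarray  # boolean grid (empty if no voxel above threshold)
    polarized_ids: set[int]


class RayCaster:
    """Casts rays on one grid; precomputes voxel-centre coordinates once."""

    def __init__(self, dims: tuple[int, int, int], spacing: VoxelSpacing) -> None:
        self.dims = tuple(dims)
        self.spacing = spacing
        sp = spacing.as_um.astype(np.float32)
        self._coords = [
            ((np.arange(dims[k], dtype=np.float32) + 0.5) * sp[k]).reshape(
                [-1 if i == k else 1 for i in range(3)]
            )
            for k in range(3)
        ]

    def perpendicular_distance(self, axis: PrincipalAxis) -> np.ndarray:
        """Per-voxel perpendicular distance (µm) to the cell's axis line."""
        c = np.asarray(axis.centroid_um, dtype=np.float32)
        a = np.asarray(axis.direction, dtype=np.float32)
        a = a / np.linalg.norm(a)
        r2 = np.zeros(self.dims, dtype=np.float32)
        proj = np.zeros(self.dims, dtype=np.float32)
        for k in range(3):
            dk = self._coords[k] - c[k]
            r2 += dk * dk
            proj += a[k] * dk
        d2 = np.maximum(r2 - proj * proj, 0.0)
        return np.sqrt(d2)

    def footprint(self, axis: PrincipalAxis, params: RayParams) -> np.ndarray:
        """Dense intensity grid of one cell's ray (0 outside the radius)."""
        d = self.perpendicular_distance(axis)
        out = params.falloff(d, params.radius_um).astype(np.float32)
        out[d >= params.radius_um] = 0.0
        return out


def ray_footprint(
    axis: PrincipalAxis,
    params: RayParams,
    dims: tuple[int, int, int],
    spacing: VoxelSpacing,
) -> np.ndarray:
    """One cell's ray footprint on the grid (see :class:`RayCaster`).

    Degenerate (ambiguous-axis) cells are skipped: their contribution is a
    zero grid, with a warning.
    """
    if axis.degenerate:
        warnings.warn(f"cell {axis.label_id}: ambiguous axis; ray skipped", stacklevel=2)
        return np.zeros(dims, dtype=np.float32)
    return RayCaster(dims, spacing).footprint(axis, params)


def line_voxels(
    axis: PrincipalAxis, dims: tuple[int, int, int], spacing: VoxelSpacing
) -> np.ndarray:
    """Integer voxel traversal of the central ray line clipped to the grid.

    3D integer line rasterization (driving-axis stepping at sub-voxel
    increments, duplicates removed) of the infinite line through the
    centroid along ±direction.
    """
    sp = spacing.as_um
    c = np.asarray(axis.centroid_um) / sp - 0.5  # index space
    a = np.asarray(axis.direction) / sp
    a = a / np.max(np.abs(a))  # one step advances the driving axis by 1 voxel
    bounds = np.asarray(dims)
    ts = []
    for k in range(3):  # clip the line to the index box
        if abs(a[k]) > 1e-12:
            ts.extend([(-0.5 - c[k]) / a[k], (bounds[k] - 0.5 - c[k]) / a[k]])
    if not ts:
        return np.empty((0, 3), dtype=int)
    t0, t1 = min(ts), max(ts)
    steps = np.arange(np.floor(t0), np.ceil(t1) + 0.5, 0.5)
    pts = np.rint(c[None, :] + steps[:, None] * a[None, :]).astype(int)
    inside = np.all((pts >= 0) & (pts < bounds), axis=1)
    pts = pts[inside]
    if pts.size == 0:
        return pts.reshape(0, 3)
    return np.unique(pts, axis=0)


def accumulate_rays(footprints: Iterable[np.ndarray]) -> np.ndarray:
    """Voxel-wise sum of per-cell ray footprints (order-invariant, additive)."""
    acc = None
    for fp in footprints:
        if acc is None:
            acc = np.zeros_like(fp, dtype=np.float32)
        if fp.shape != acc.shape:
            raise ValueError(f"footprint grid {fp.shape} does not match {acc.shape}")
        acc += fp
    if acc is None:
        raise ValueError("no footprints given")
    return acc


def accumulation_map(
    axes: Sequence[PrincipalAxis],
    dims: tuple[int, int, int],
    spacing: VoxelSpacing,
    params: RayParams = RayParams(),
) -> np.ndarray:
    """Accumulated ray intensity of a set of cells (streaming; one grid in memory)."""
    caster = RayCaster(dims, spacing)
    acc = np.zeros(dims, dtype=np.float32)
    for ax in axes:
        if ax.degenerate:
            warnings.warn(f"cell {ax.label_id}: ambiguous axis; ray skipped", stacklevel=2)
            continue
        acc += caster.footprint(ax, params)
    return acc


def extract_hotspot(accumulation: np.ndarray, threshold: float) -> np.ndarray:
    """Largest 26-connected component of voxels with accumulation > threshold.

    Returns a boolean mask (all False when nothing exceeds the threshold).
    The strict inequality follows the convergence criterion "accumulated ray
    intensity > 3.5".
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    above = accumulation > threshold
    if not above.any():
        return np.zeros_like(above)
    comps, n = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=bool))
    sizes = np.bincount(comps.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1  # ties: first (lowest) component id
    return comps == largest


def classify_polarized(
    axes: Sequence[PrincipalAxis],
    hotspot_mask: np.ndarray,
    params: RayParams,
    spacing: VoxelSpacing,
) -> set[int]:
    """Cells whose ray footprint reaches the hot spot.

    A cell is polarized iff at least one hot-spot voxel carries nonzero ray
    intensity from that cell, i.e. its axis line passes within the ray
    radius of the voxel's centre.  Evaluated at hot-spot voxels only.
    """
    idx = np.argwhere(hotspot_mask)
    if idx.size == 0:
        return set()
    pos = (idx + 0.5) * spacing.as_um  # (m, 3) µm
    out: set[int] = set()
    for ax in axes:
        if ax.degenerate:
            continue
        c = np.asarray(ax.centroid_um)
        a = np.asarray(ax.direction)
        rel = pos - c
        proj = rel @ a
        d2 = np.sum(rel * rel, axis=1) - proj * proj
        d = np.sqrt(np.maximum(d2, 0.0))
        if np.any(params.falloff(d, params.radius_um) > 0):
            out.add(ax.label_id)
    return out


def run_polarity(
    axes: Sequence[PrincipalAxis],
    dims: tuple[int, int, int],
    spacing: VoxelSpacing,
    params: RayParams = RayParams(),
) -> PolarityResult:
    """Full polarity analysis: accumulate rays, extract the hot spot, classify cells."""
    acc = accumulation_map(axes, dims, spacing, params)
    hotspot = extract_hotspot(acc, params.threshold)
    polarized = classify_polarized(axes, hotspot, params, spacing)
    return PolarityResult(accumulation=acc, hotspot_mask=hotspot, polarized_ids=polarized)
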