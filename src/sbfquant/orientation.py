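"""Main-axis extraction (PCA) and the best-fit alignment plane.

Each structure's *main axis* is the leading principal component of its voxel
centres in physical coordinates; axes are unsigned directions (a and -a are
the same axis), canonicalised so that the first nonzero component is
positive.  The bundle of cell axes defines a best *alignment plane*: the
plane whose normal n minimises the axial least-squares objective

    sum_i (n . a_i)^2  =  sum_i sin^2(theta_i),

where theta_i is the inclination of axis i out of the plane.  The minimiser
is the eigenvector of the smallest eigenvalue of M = sum_i a_i a_i^T.
Inclination angles are reported in degrees in [0, 90].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import cell_body_mask
from .volume_model import LabelVolume, SegmentTable, VoxelSpacing

#: relative eigenvalue gap below which an axis/normal is flagged ambiguous
DEGENERACY_RTOL = 1e-6


@dataclass(frozen=True)
class PrincipalAxis:
    label_id: int
    centroid_um: tuple[float, float, float]
    direction: tuple[float, float, float]  # unit, canonical sign
    eigenvalues_um2: tuple[float, float, float]  # descending
    degenerate: bool = False

    @property
    def direction_array(self) -> np.ndarray:
        return np.array(self.direction)


@dataclass
class AlignmentPlane:
    normal: np.ndarray  # unit, canonical sign
    objective: float  # sum_i (normal . axis_i)^2 over fitted axes
    inclinations_deg: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False


def _canonical_sign(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    for comp in v:
        if abs(comp) > tol:
            return v if comp > 0 else -v
    return v


def principal_axis(mask: np.ndarray, spacing: VoxelSpacing, label_id: int = 0) -> PrincipalAxis:
    """Leading PCA axis of a structure's voxel centres in physical units.

    The covariance of the voxel-centre coordinates (µm, population
    convention) is eigen-decomposed; the direction is the leading
    eigenvector with canonical sign.  A near-tie between the two largest
    eigenvalues flags the axis as ambiguous.  Translation-invariant and
    equivariant under rotations of the grid.
    """
    idx = np.argwhere(mask)
    if idx.shape[0] < 4:
        raise ValueError(f"mask has {idx.shape[0]} voxels; need at least 4")
    coords = (idx + 0.5) * spacing.as_um
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = (centred.T @ centred) / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    degenerate = bool(evals[0] - evals[1] <= DEGENERACY_RTOL * max(evals[0], 1e-30))
    if degenerate:
        warnings.warn(f"label {label_id}: ambiguous axis (lambda1 ~ lambda2)", stacklevel=2)
    direction = _canonical_sign(evecs[:, 0])
    return PrincipalAxis(
        label_id=label_id,
        centroid_um=tuple(float(c) for c in centroid),
        direction=tuple(float(c) for c in direction),
        eigenvalues_um2=tuple(float(v) for v in evals),
        degenerate=degenerate,
    )


def axes_from_labels(
    labels: LabelVolume,
    segments: SegmentTable,
    segment_class: str = "cell",
    ids: list[int] | None = None,
) -> list[PrincipalAxis]:
    """Principal axes for every structure of a class (cells use the whole body)."""
    out = []
    for lid in (ids if ids is not None else segments.ids_of_class(segment_class)):
        if segment_class == "cell":
            mask = cell_body_mask(labels, segments, lid)
        else:
            mask = labels.mask(lid)
        if mask.sum() < 4:
            warnings.warn(f"label {lid}: too few voxels for an axis; skipped", stacklevel=2)
            continue
        out.append(principal_axis(mask, labels.spacing, label_id=lid))
    return out


def fit_alignment_plane(
    axes: list[PrincipalAxis],
    extra_axes: list[PrincipalAxis] | None = None,
) -> AlignmentPlane:
    """Best alignment plane of a bundle of unsigned axes (axial least squares).

    The returned normal minimises ``sum_i (n . a_i)^2`` exactly (smallest
    eigenvector of the axis scatter matrix).  Inclinations are computed for
    every fitted axis and for any ``extra_axes`` (e.g. nuclei or capillary
    portions scored against the cells' plane without influencing the fit).
    """
    if len(axes) < 3:
        raise ValueError(f"need at least 3 axes to fit a plane, got {len(axes)}")
    A = np.array([ax.direction for ax in axes])
    M = A.T @ A
    evals, evecs = np.linalg.eigh(M)  # ascending
    degenerate = bool(evals[1] - evals[0] <= DEGENERACY_RTOL * max(evals[-1], 1e-30))
    if degenerate:
        warnings.warn("degenerate alignment plane (tied smallest eigenvalues)", stacklevel=2)
    normal = _canonical_sign(evecs[:, 0])
    plane = AlignmentPlane(
        normal=normal,
        objective=float(np.sum((A @ normal) ** 2)),
        degenerate=degenerate,
    )
    for ax in axes + list(extra_axes or []):
        plane.inclinations_deg[ax.label_id] = inclination_angle(ax.direction_array, plane)
    return plane


def inclination_angle(axis: np.ndarray, plane: AlignmentPlane) -> float:
    """Angle between an unsigned unit axis and the plane, degrees in [0, 90]."""
    s = abs(float(np.dot(axis, plane.normal)))
    return float(np.degrees(np.arcsin(min(s, 1.0))))


@dataclass(frozen=True)
class AngleHistogram:
    bin_edges_deg: tuple[float, ...]
    counts: tuple[int, ...]
    share_0_20: float
    n: int


def angle_histogram(angles_deg) -> AngleHistogram:
    """Histogram of inclination angles in 10° bins over [0, 90].

    The last bin is closed at 90°.  ``share_0_20`` is the fraction of angles
    ≤ 20° (inclusive — an angle of exactly 20° counts toward the share but
    falls in the [20, 30) bin).
    """
    angles = np.asarray(list(angles_deg), dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list: share_0_20 undefined")
    if np.any(angles < 0) or np.any(angles > 90):
        raise ValueError("angles must lie in [0, 90] degrees")
    edges = np.arange(0.0, 100.0, 10.0)
    counts, _ = np.histogram(angles, bins=edges)
    return AngleHistogram(
        bin_edges_deg=tuple(edges),
        counts=tuple(int(c) for c in counts),
        share_0_20=float(np.mean(angles <= 20.0)),
        n=int(angles.size),
    )


def axes_to_frame(axes: list[PrincipalAxis]) -> pd.DataFrame:
    """Axes as a tidy table (for CSV export and joins)."""
    return pd.DataFrame(
        [
            {
                "label_id": ax.label_id,
                "centroid_x_um": ax.centroid_um[0],
                "centroid_y_um": ax.centroid_um[1],
                "centroid_z_um": ax.centroid_um[2],
                "dir_x": ax.direction[0],
                "dir_y": ax.direction[1],
                "dir_z": ax.direction[2],
                "lambda1_um2": ax.eigenvalues_um2[0],
                "lambda2_um2": ax.eigenvalues_um2[1],
                "lambda3_um2": ax.eigenvalues_um2[2],
                "degenerate": ax.degenerate,
            }
            for ax in axes
        ]
    )
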