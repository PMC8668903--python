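"""Volumes, centroids, completeness and compartment composition of labelled structures.

All measurements are taken on voxel-centre physical coordinates with the
anisotropic spacing applied, so a structure's volume is
``voxel_count * dx * dy * dz`` (nm³ converted to µm³) and its centroid is the
mean of voxel centres in µm.  A structure is *complete* when none of its
voxels lies on one of the six stack faces; the analysis keeps tumour cells
with a complete nucleus (optionally also requiring the cell body itself to be
complete).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_model import (
    MEASUREMENT_COLUMNS,
    LabelVolume,
    SegmentTable,
    VoxelSpacing,
    empty_measurements,
)


@dataclass(frozen=True)
class StructureMorphometry:
    label_id: int
    segment_class: str
    voxel_count: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    touches_boundary: bool


@dataclass(frozen=True)
class CellComposition:
    """Volumetric breakdown of one cell into nucleus / cytoplasm / mitochondria.

    Cytoplasm is derived as cell minus nucleus (the segmented cell volume is
    the whole cell body); mitochondria live inside the cytoplasmic
    compartment.  The nucleocytoplasmic ratio is nucleus/cytoplasm.
    """

    cell_id: int
    cell_volume_um3: float
    nucleus_volume_um3: float
    cytoplasm_volume_um3: float
    mito_total_volume_um3: float
    nucleocytoplasmic_ratio: float
    mito_fraction: float


def measure_structure(labels: LabelVolume, label_id: int,
                      segment_class: str = "cell") -> StructureMorphometry:
    """Voxel count, physical volume, centroid and boundary flag of one label."""
    mask = labels.mask(label_id)
    count = int(mask.sum())
    if count == 0:
        raise KeyError(f"label {label_id} not present in volume")
    idx = np.argwhere(mask)
    spacing_um = labels.spacing.as_um
    centroid = (idx.mean(axis=0) + 0.5) * spacing_um
    dims = np.asarray(labels.dims)
    touches = bool(np.any(idx == 0) or np.any(idx == dims - 1))
    return StructureMorphometry(
        label_id=label_id,
        segment_class=segment_class,
        voxel_count=count,
        volume_um3=count * labels.spacing.voxel_volume_um3,
        centroid_um=tuple(float(c) for c in centroid),
        touches_boundary=touches,
    )


def measure_all(labels: LabelVolume, segments: SegmentTable) -> pd.DataFrame:
    """Measurement table for every labelled structure (vectorised over labels).

    Returns the canonical measurement table; columns filled by later stages
    (distances, inclinations, polarity) are initialised to NaN/False.
    """
    arr = labels.labels
    flat = arr.ravel()
    max_id = int(flat.max()) if flat.size else 0
    counts = np.bincount(flat, minlength=max_id + 1)
    spacing_um = labels.spacing.as_um

    # per-label centroid via weighted bincounts of index coordinates
    ix, iy, iz = np.indices(arr.shape, sparse=True)
    sums = [
        np.bincount(flat, weights=np.broadcast_to(coord, arr.shape).ravel(), minlength=max_id + 1)
        for coord in (ix, iy, iz)
    ]
    boundary_ids: set[int] = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary_ids.update(int(v) for v in np.unique(arr[tuple(sl)]))

    def stats_for(ids: list[int]) -> tuple[int, np.ndarray, bool]:
        n = sum(int(counts[i]) for i in ids if i <= max_id)
        if n == 0:
            return 0, np.zeros(3), False
        csum = np.array([sum(s[i] for i in ids if i <= max_id) for s in sums])
        touches = any(i in boundary_ids for i in ids)
        return n, csum / n, touches

    rows = []
    for rec in segments:
        lid = rec.label_id
        # a cell's voxels are split between its own id (cytoplasm) and its
        # children's ids; the cell row reports the whole body
        ids = [lid] + (segments.children_of(lid) if rec.segment_class == "cell" else [])
        n, centroid, touches = stats_for(ids)
        if n == 0:
            continue
        centroid = (centroid + 0.5) * spacing_um
        rows.append({
            "label_id": lid,
            "class": rec.segment_class,
            "voxel_count": n,
            "volume_um3": n * labels.spacing.voxel_volume_um3,
            "centroid_x_um": centroid[0],
            "centroid_y_um": centroid[1],
            "centroid_z_um": centroid[2],
            "complete": not touches,
            "complete_nucleus": False,
            "distance_to_capillary_um": np.nan,
            "centroid_distance_um": np.nan,
            "inclination_deg": np.nan,
            "polarized": False,
        })
    if not rows:
        return empty_measurements()
    table = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    return _fill_complete_nucleus(table, segments)


def _fill_complete_nucleus(table: pd.DataFrame, segments: SegmentTable) -> pd.DataFrame:
    complete = dict(zip(table["label_id"], table["complete"]))
    out = table.copy()
    for i, row in out.iterrows():
        if row["class"] != "cell":
            continue
        nuc = segments.nucleus_of(int(row["label_id"]))
        out.at[i, "complete_nucleus"] = bool(nuc is not None and complete.get(nuc, False))
    return out


def derive_composition(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    mito_mask: np.ndarray,
    spacing: VoxelSpacing,
    cell_id: int = 0,
) -> CellComposition:
    """Compartment volumes and ratios from one cell's component masks.

    Requires nucleus ⊂ cell and mitochondria ⊂ cytoplasm (inside the cell,
    outside the nucleus); a containment violation raises with the offending
    voxel count.
    """
    bad_nuc = int(np.count_nonzero(nucleus_mask & ~cell_mask))
    if bad_nuc:
        raise ValueError(f"nucleus has {bad_nuc} voxels outside the cell")
    bad_mito = int(np.count_nonzero(mito_mask & ~cell_mask))
    if bad_mito:
        raise ValueError(f"mitochondria have {bad_mito} voxels outside the cell")
    bad_mito_nuc = int(np.count_nonzero(mito_mask & nucleus_mask))
    if bad_mito_nuc:
        raise ValueError(f"mitochondria have {bad_mito_nuc} voxels inside the nucleus")
    vv = spacing.voxel_volume_um3
    cell_v = int(cell_mask.sum()) * vv
    nuc_v = int(nucleus_mask.sum()) * vv
    cyto_v = cell_v - nuc_v
    mito_v = int(mito_mask.sum()) * vv
    return CellComposition(
        cell_id=cell_id,
        cell_volume_um3=cell_v,
        nucleus_volume_um3=nuc_v,
        cytoplasm_volume_um3=cyto_v,
        mito_total_volume_um3=mito_v,
        nucleocytoplasmic_ratio=nuc_v / cyto_v if cyto_v > 0 else np.inf,
        mito_fraction=mito_v / cell_v if cell_v > 0 else 0.0,
    )


def compose_all(labels: LabelVolume, segments: SegmentTable) -> pd.DataFrame:
    """Per-cell composition table (one row per cell with a nucleus record).

    Compartments are derived from label ids and parentage: the cell body is
    the union of the cell label with its nucleus and mitochondria labels.
    """
    vv = labels.spacing.voxel_volume_um3
    arr = labels.labels
    counts = np.bincount(arr.ravel(), minlength=int(arr.max()) + 1 if arr.size else 1)
    rows = []
    for cid in segments.ids_of_class("cell"):
        nuc = segments.nucleus_of(cid)
        if nuc is None:
            warnings.warn(f"cell {cid} has no nucleus record; skipped", stacklevel=2)
            continue
        mito_ids = segments.children_of(cid, "mitochondrion")
        cyto_voxels = int(counts[cid]) if cid < len(counts) else 0
        nuc_voxels = int(counts[nuc]) if nuc < len(counts) else 0
        mito_voxels = sum(int(counts[m]) for m in mito_ids if m < len(counts))
        cell_voxels = cyto_voxels + nuc_voxels + mito_voxels
        if cell_voxels == 0:
            continue
        cyto_total = (cyto_voxels + mito_voxels) * vv  # cytoplasm = cell minus nucleus
        rows.append({
            "cell_id": cid,
            "cell_volume_um3": cell_voxels * vv,
            "nucleus_volume_um3": nuc_voxels * vv,
            "cytoplasm_volume_um3": cyto_total,
            "mito_total_volume_um3": mito_voxels * vv,
            "nucleocytoplasmic_ratio": (nuc_voxels * vv) / cyto_total if cyto_total else np.inf,
            "mito_fraction": mito_voxels / cell_voxels,
        })
    return pd.DataFrame(
        rows,
        columns=["cell_id", "cell_volume_um3", "nucleus_volume_um3", "cytoplasm_volume_um3",
                 "mito_total_volume_um3", "nucleocytoplasmic_ratio", "mito_fraction"],
    )


def cell_body_mask(labels: LabelVolume, segments: SegmentTable, cell_id: int) -> np.ndarray:
    """Boolean mask of a whole cell body (cell label + nucleus + mitochondria)."""
    ids = [cell_id] + segments.children_of(cell_id)
    return np.isin(labels.labels, ids)


def select_complete(table: pd.DataFrame, segments: SegmentTable,
                    mode: str = "cell_and_nucleus") -> pd.DataFrame:
    """Filter the measurement table to analysable cells.

    ``mode="cell_and_nucleus"`` keeps cells whose own mask and whose nucleus
    mask are both off-boundary (fully contained cells); ``mode="nucleus_only"``
    keeps any cell whose nucleus is complete regardless of the cell body (the
    criterion used for the orientation analysis).  Cells without a nucleus
    record are excluded with a warning.
    """
    if mode not in ("cell_and_nucleus", "nucleus_only"):
        raise ValueError(f"unknown mode {mode!r}")
    cells = table[table["class"] == "cell"]
    keep = []
    for _, row in cells.iterrows():
        cid = int(row["label_id"])
        if segments.nucleus_of(cid) is None:
            warnings.warn(f"cell {cid} has no nucleus record; excluded", stacklevel=2)
            continue
        if not row["complete_nucleus"]:
            continue
        if mode == "cell_and_nucleus" and not row["complete"]:
            continue
        keep.append(cid)
    return table[table["label_id"].isin(keep)].reset_index(drop=True)
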