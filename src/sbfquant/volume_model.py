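"""Core containers and I/O for serial block-face EM stacks and label volumes.

The in-memory convention throughout the package:

* arrays are indexed ``[ix, iy, iz]`` with shape ``(nx, ny, nz)``; ``iz`` runs
  along the sectioning (block-face) axis;
* voxel indices are 0-based and a voxel's physical position is the position of
  its *centre*: ``((ix + 0.5) * dx, (iy + 0.5) * dy, (iz + 0.5) * dz)``;
* spacings are stored in nanometres, positions/distances are reported in
  micrometres, volumes in µm³.

Multi-page TIFF files store one section per page (``(nz, ny, nx)`` on disk);
readers/writers transpose between the two layouts.  Voxel spacing is never
inferred from TIFF tags — dialects vary — it is always explicit input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("sbfquant")

NM_PER_UM = 1000.0

#: recognised structure classes in a segment table
SEGMENT_CLASSES = (
    "cell",
    "nucleus",
    "mitochondrion",
    "cytoplasm",
    "capillary",
    "immune_cell",
    "red_blood_cell",
)

#: fixed column order of a measurement table CSV
MEASUREMENT_COLUMNS = (
    "label_id",
    "class",
    "voxel_count",
    "volume_um3",
    "centroid_x_um",
    "centroid_y_um",
    "centroid_z_um",
    "complete",
    "complete_nucleus",
    "distance_to_capillary_um",
    "centroid_distance_um",
    "inclination_deg",
    "polarized",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelSpacing:
    """Anisotropic voxel spacing in nanometres.

    SBF-SEM stacks typically have much finer lateral than axial sampling
    (e.g. 15x15 nm in-plane versus 100 nm section thickness), so ``dz`` may
    greatly exceed ``dx`` and ``dy``.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self}")

    @property
    def as_nm(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    @property
    def as_um(self) -> np.ndarray:
        return self.as_nm / NM_PER_UM

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.as_um))


@dataclass
class IntensityStack:
    """A 3D grayscale EM stack, ``values[ix, iy, iz]`` with physical spacing."""

    values: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"stack must be 3D with positive dims, got shape {self.values.shape}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def nz(self) -> int:
        return self.values.shape[2]

    def slice(self, iz: int) -> np.ndarray:
        """The 2D section at depth index ``iz`` (a view, ``[ix, iy]``)."""
        return self.values[:, :, iz]


@dataclass
class LabelVolume:
    """A 3D integer label grid; 0 is background, every other id is a structure."""

    labels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-valued, got dtype {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_ids(self) -> np.ndarray:
        """Sorted array of nonzero label ids present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


@dataclass(frozen=True)
class SegmentRecord:
    """One row of the tissue inventory: a labelled structure and its class."""

    label_id: int
    segment_class: str
    parent_id: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.segment_class not in SEGMENT_CLASSES:
            raise ValueError(
                f"unknown segment class {self.segment_class!r}; expected one of {SEGMENT_CLASSES}"
            )


class SegmentTable:
    """Per-label records mapping label id -> structure class (+ parentage).

    Nuclei and mitochondria carry a ``parent_id`` pointing at their owning
    cell; the parent's class must be ``cell``.
    """

    def __init__(self, records: Iterable[SegmentRecord] = ()) -> None:
        self._records: dict[int, SegmentRecord] = {}
        for rec in records:
            self.add(rec)
        self._validate_parents()

    def add(self, rec: SegmentRecord) -> None:
        if rec.label_id in self._records:
            raise ValueError(f"duplicate label_id {rec.label_id}")
        if rec.label_id <= 0:
            raise ValueError("label_id must be positive (0 is background)")
        self._records[rec.label_id] = rec

    def _validate_parents(self) -> None:
        for rec in self._records.values():
            if rec.parent_id is not None:
                parent = self._records.get(rec.parent_id)
                if parent is None:
                    raise ValueError(f"label {rec.label_id}: parent {rec.parent_id} not in table")
                if parent.segment_class != "cell":
                    raise ValueError(
                        f"label {rec.label_id}: parent {rec.parent_id} has class "
                        f"{parent.segment_class!r}, expected 'cell'"
                    )

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, label_id: int) -> bool:
        return label_id in self._records

    def __getitem__(self, label_id: int) -> SegmentRecord:
        return self._records[label_id]

    def __iter__(self):
        return iter(sorted(self._records.values(), key=lambda r: r.label_id))

    def ids_of_class(self, segment_class: str) -> list[int]:
        return sorted(r.label_id for r in self._records.values() if r.segment_class == segment_class)

    def children_of(self, cell_id: int, segment_class: str | None = None) -> list[int]:
        out = [
            r.label_id
            for r in self._records.values()
            if r.parent_id == cell_id
            and (segment_class is None or r.segment_class == segment_class)
        ]
        return sorted(out)

    def nucleus_of(self, cell_id: int) -> int | None:
        nuclei = self.children_of(cell_id, "nucleus")
        return nuclei[0] if nuclei else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label_id": r.label_id,
                "class": r.segment_class,
                "parent_id": r.parent_id if r.parent_id is not None else -1,
                "notes": r.notes,
            }
            for r in self
        ]
        return pd.DataFrame(rows, columns=["label_id", "class", "parent_id", "notes"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SegmentTable":
        required = {"label_id", "class"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"segment table missing required columns: {sorted(missing)}")
        records = []
        for _, row in df.iterrows():
            parent = row.get("parent_id", -1)
            parent_id = None if pd.isna(parent) or int(parent) < 0 else int(parent)
            notes = row.get("notes", "")
            records.append(
                SegmentRecord(
                    label_id=int(row["label_id"]),
                    segment_class=str(row["class"]),
                    parent_id=parent_id,
                    notes="" if pd.isna(notes) else str(notes),
                )
            )
        return cls(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SegmentTable":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# stack / label I/O
# ---------------------------------------------------------------------------


def _read_pages(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into a ``(nx, ny, nz)`` array, checking shapes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"ragged stack: pages have differing shapes {sorted(shapes)}")
        pages = tif.asarray()
    if pages.ndim == 2:  # single page
        pages = pages[None]
    # disk layout (nz, ny, nx) -> memory layout (nx, ny, nz)
    return np.ascontiguousarray(pages.transpose(2, 1, 0))


def load_stack(path: str | Path, spacing: VoxelSpacing) -> IntensityStack:
    """Load a grayscale multi-page TIFF as an :class:`IntensityStack`.

    Values are preserved bit-exactly; ``nz`` equals the page count.
    """
    values = _read_pages(path)
    if not (np.issubdtype(values.dtype, np.integer) or np.issubdtype(values.dtype, np.floating)):
        raise ValueError(f"unsupported sample format {values.dtype}")
    return IntensityStack(values=values, spacing=spacing)


def save_stack(stack: IntensityStack, path: str | Path) -> None:
    """Write an :class:`IntensityStack` as a multi-page TIFF (one page per section)."""
    tifffile.imwrite(Path(path), np.ascontiguousarray(stack.values.transpose(2, 1, 0)),
                     photometric="minisblack")


def save_labels(volume: LabelVolume, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.ascontiguousarray(volume.labels.transpose(2, 1, 0)),
                     photometric="minisblack")


def load_labels(path: str | Path, spacing: VoxelSpacing) -> LabelVolume:
    values = _read_pages(path)
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError(f"label TIFF must be integer-valued, got {values.dtype}")
    return LabelVolume(labels=values, spacing=spacing)


def validate_pair(volume: LabelVolume, table: SegmentTable) -> None:
    """Cross-validate a label volume against its segment table.

    Every nonzero label in the volume must have a table record; ids present in
    the table but absent from the volume are tolerated (a structure may have
    been cropped away) but reported at debug level.
    """
    present = set(int(i) for i in volume.label_ids())
    known = {r.label_id for r in table}
    orphans = sorted(present - known)
    if orphans:
        raise ValueError(f"labels present in volume but absent from table: {orphans}")
    unused = sorted(known - present)
    if unused:
        logger.debug("segment table ids with no voxels in volume: %s", unused)


def load_segmentation(
    label_path: str | Path, table_path: str | Path, spacing: VoxelSpacing
) -> tuple[LabelVolume, SegmentTable]:
    """Load a label TIFF plus its CSV segment table and cross-validate them."""
    volume = load_labels(label_path, spacing)
    table = SegmentTable.from_csv(table_path)
    validate_pair(volume, table)
    return volume, table


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


def empty_measurements() -> pd.DataFrame:
    """An empty measurement table with the canonical columns."""
    return pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))


def save_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as CSV in fixed column order.

    Floats are written with 6 significant digits; a save→load round trip is
    lossless at that precision.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    table[list(MEASUREMENT_COLUMNS)].to_csv(path, index=False, float_format="%.6g")


def load_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV missing columns: {missing}")
    for flag in ("complete", "complete_nucleus", "polarized"):
        if len(df):
            df[flag] = df[flag].astype(bool)
    return df[list(MEASUREMENT_COLUMNS)]


def write_manifest(
    path: str | Path,
    spacing: VoxelSpacing,
    seed: int | None = None,
    parameters: Mapping[str, object] | None = None,
) -> None:
    """Write a JSON run manifest recording spacing, parameters and seed."""
    from . import __version__

    manifest = {
        "software": "sbfquant",
        "version": __version__,
        "spacing_nm": [spacing.dx, spacing.dy, spacing.dz],
        "seed": seed,
        "parameters": dict(parameters or {}),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
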