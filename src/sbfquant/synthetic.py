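"""Synthetic tumour-tissue scenes with exact ground truth.

No raw SBF-SEM stacks are available for this kind of study at desk scale, so
every quantitative stage of the pipeline is exercised against generated
scenes whose geometry is known analytically:

* tumour cells are triaxial ellipsoids (prolate, aspect ratio 1.5–3 so the
  major axis is well defined and equals the leading PCA axis exactly);
* each cell carries a concentric nucleus (a scaled copy of its ellipsoid,
  default 32% of the cell volume, the ratio observed in a fully segmented
  hepatoblastoma cell: 313.6 / 970.6 µm³) and small spherical mitochondria in
  the cytoplasmic shell;
* an optional blood capillary is a straight cylinder of given radius;
* cell main axes follow one of three orientation models: isotropic,
  plane-aligned (wrapped-normal tilt about a common plane) or hotspot-aimed
  (a fixed fraction of cells points at a common convergence point);
* an optional radius-versus-capillary-distance slope couples cell size to
  vascular proximity.

The generator records per-cell truth (centre, semi-axes, axis, polarized
flag, capillary distance, completeness) so downstream estimators can be
tested for parameter recovery rather than merely for self-consistency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume_model import IntensityStack, LabelVolume, SegmentRecord, SegmentTable, VoxelSpacing

logger = logging.getLogger("sbfquant")

#: label-id blocks (desk scale: fewer than 1000 cells per scene)
NUCLEUS_ID_OFFSET = 1000
MITO_ID_OFFSET = 2000
CAPILLARY_ID = 9001


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Isotropic:
    """Cell axes drawn uniformly on the sphere."""


@dataclass(frozen=True)
class PlaneAligned:
    """Cell axes tilted out of a common plane by a wrapped-normal angle.

    ``normal`` is the plane normal; the tilt angle (degrees) is drawn from
    N(0, sigma_deg), so the inclination of a true axis relative to the plane
    is the folded wrapped-normal |phi|.
    """

    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sigma_deg: float = 10.0


@dataclass(frozen=True)
class Hotspot:
    """A fixed fraction of cells aim their axis at a common point.

    ``round(fraction * n_cells)`` cells (the first ones generated) point at
    ``point_um`` with an angular perturbation of sigma_deg; the rest are
    isotropic.  Aimed cells carry the true ``polarized`` flag.
    """

    point_um: tuple[float, float, float]
    fraction: float = 0.4
    sigma_deg: float = 5.0


OrientationModel = Isotropic | PlaneAligned | Hotspot


@dataclass(frozen=True)
class CapillarySpec:
    """A straight cylindrical capillary between two endpoints (µm)."""

    p0_um: tuple[float, float, float]
    p1_um: tuple[float, float, float]
    radius_um: float = 2.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic tumour scene.

    Desk-scale defaults: a 256x256x64 grid at 150x150x300 nm spacing
    (38.4 x 38.4 x 19.2 µm of tissue) keeps every stage fast while preserving
    the lateral/axial anisotropy of block-face imaging.  Physical formulas
    downstream are scale-free.
    """

    dims: tuple[int, int, int] = (256, 256, 64)
    spacing: VoxelSpacing = VoxelSpacing(150.0, 150.0, 300.0)
    n_cells: int = 30
    cell_radius_mean_um: float = 3.5
    cell_radius_sd_um: float = 0.6
    aspect_ratio_range: tuple[float, float] = (1.5, 3.0)
    nucleus_volume_fraction: float = 0.32
    mito_per_cell: tuple[int, int] = (20, 40)
    mito_radius_um: float = 0.25
    orientation_model: OrientationModel = Isotropic()
    capillary: CapillarySpec | None = None
    size_distance_beta: float = 0.0
    #: when True, cell centres are kept at least one major radius away from
    #: every face, so all cells are fully contained (recovery experiments)
    contain_cells: bool = False
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 < self.nucleus_volume_fraction < 1:
            raise ValueError("nucleus_volume_fraction must lie in (0, 1)")
        if isinstance(self.orientation_model, Hotspot):
            if not 0 <= self.orientation_model.fraction <= 1:
                raise ValueError("hotspot fraction must lie in [0, 1]")
        sigma = getattr(self.orientation_model, "sigma_deg", 0.0)
        if sigma < 0:
            raise ValueError("sigma_deg must be >= 0")
        lo, hi = self.mito_per_cell
        if lo < 0 or hi < lo:
            raise ValueError("mito_per_cell must be a non-negative (lo, hi) range")

    @property
    def extent_um(self) -> np.ndarray:
        return np.array(self.dims) * self.spacing.as_um


@dataclass
class GroundTruth:
    """Per-cell generative truth plus scene-level orientation parameters."""

    cells: pd.DataFrame
    plane_normal: np.ndarray | None = None
    hotspot_um: np.ndarray | None = None
    jitter: pd.DataFrame | None = None


@dataclass
class SyntheticScene:
    labels: LabelVolume
    segments: SegmentTable
    truth: GroundTruth
    config: SceneConfig


# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero vector")
    return np.asarray(v, dtype=float) / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to unit vector ``v``."""
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(v)))] = 1.0
    return _unit(np.cross(v, helper))


def _frame(axis: np.ndarray) -> np.ndarray:
    """Orthonormal frame with first column ``axis`` (columns = principal dirs)."""
    a = _unit(axis)
    b = _any_perpendicular(a)
    c = np.cross(a, b)
    return np.column_stack([a, b, c])


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = float(np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def sample_axis(
    model: OrientationModel, rng: np.random.Generator, center_um: np.ndarray | None = None,
    aimed: bool = False,
) -> np.ndarray:
    """Draw one true (unsigned) main-axis direction under an orientation model."""
    if isinstance(model, PlaneAligned):
        n = _unit(np.array(model.normal, dtype=float))
        raw = rng.standard_normal(3)
        in_plane = raw - np.dot(raw, n) * n
        while np.linalg.norm(in_plane) < 1e-12:  # pragma: no cover - measure-zero
            raw = rng.standard_normal(3)
            in_plane = raw - np.dot(raw, n) * n
        u = _unit(in_plane)
        phi = np.deg2rad(rng.normal(0.0, model.sigma_deg))
        return u * np.cos(phi) + n * np.sin(phi)
    if isinstance(model, Hotspot) and aimed:
        if center_um is None:
            raise ValueError("hotspot model needs the cell centre")
        d0 = _unit(np.asarray(model.point_um) - center_um)
        w = _any_perpendicular(d0)
        # random roll of the perpendicular so the perturbation cone is symmetric
        roll = rng.uniform(0.0, 2 * np.pi)
        w = w * np.cos(roll) + np.cross(d0, w) * np.sin(roll)
        phi = np.deg2rad(rng.normal(0.0, model.sigma_deg))
        return d0 * np.cos(phi) + w * np.sin(phi)
    return _unit(rng.standard_normal(3))


def _ellipsoid_support(semi_um: np.ndarray, R: np.ndarray, u: np.ndarray) -> float:
    """Support function h(u) of an ellipsoid with semi-axes/frame (worst-case extent)."""
    return float(np.sqrt(np.sum((semi_um * (R.T @ u)) ** 2)))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _bbox_indices(center_um, half_um, dims, spacing_um):
    lo = np.floor(center_um / spacing_um - half_um / spacing_um - 1).astype(int)
    hi = np.ceil(center_um / spacing_um + half_um / spacing_um + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(dims))
    return lo, hi


def _inside_ellipsoid(center_um, semi_um, R, lo, hi, spacing_um):
    """Boolean mask over the bbox [lo, hi) of voxel centres inside the ellipsoid."""
    xs = (np.arange(lo[0], hi[0]) + 0.5) * spacing_um[0] - center_um[0]
    ys = (np.arange(lo[1], hi[1]) + 0.5) * spacing_um[1] - center_um[1]
    zs = (np.arange(lo[2], hi[2]) + 0.5) * spacing_um[2] - center_um[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    q = np.zeros_like(X)
    for k in range(3):
        t = (R[0, k] * X + R[1, k] * Y + R[2, k] * Z) / semi_um[k]
        q += t * t
    return q <= 1.0


def _paint(labels, where_mask, lo, hi, label_id, only_on=0):
    box = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    box[where_mask & (box == only_on)] = label_id


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a tumour-like label volume plus segment table and ground truth.

    Placement is sequential rejection sampling: cell centres are drawn
    uniformly over the volume and a candidate is accepted when its ellipsoid
    is separated (support-function test along the centre line, one-voxel
    margin) from every placed cell and from the capillary.  Cells may
    protrude through the stack faces; such cells are marked incomplete in the
    truth, mirroring partially contained structures in a real stack.

    Identical seeds give bit-identical scenes.
    """
    rng = np.random.default_rng(config.seed)
    dims = tuple(config.dims)
    spacing_um = config.spacing.as_um
    extent = config.extent_um
    labels = np.zeros(dims, dtype=np.int32)
    records: list[SegmentRecord] = []

    cap = config.capillary
    cap_p0 = cap_p1 = None
    if cap is not None:
        cap_p0 = np.array(cap.p0_um, dtype=float)
        cap_p1 = np.array(cap.p1_um, dtype=float)
        _rasterize_capillary(labels, cap_p0, cap_p1, cap.radius_um, spacing_um)
        records.append(SegmentRecord(CAPILLARY_ID, "capillary"))

    model = config.orientation_model
    n_aimed = int(round(model.fraction * config.n_cells)) if isinstance(model, Hotspot) else 0

    # maximum capillary distance achievable in this volume, for the size gradient
    d_ref = 1.0
    if cap is not None:
        corners = np.array(np.meshgrid([0, extent[0]], [0, extent[1]], [0, extent[2]])).T.reshape(-1, 3)
        d_ref = max(_point_segment_distance(c, cap_p0, cap_p1) for c in corners)

    placed: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # (center, semi, frame)
    margin = float(np.max(spacing_um))
    rows = []
    for i in range(config.n_cells):
        cell_id = i + 1
        aimed = i < n_aimed
        for attempt in range(config.max_attempts):
            a = float(np.clip(
                rng.normal(config.cell_radius_mean_um, config.cell_radius_sd_um),
                0.4 * config.cell_radius_mean_um, 2.0 * config.cell_radius_mean_um,
            ))
            aspect = rng.uniform(*config.aspect_ratio_range)
            if config.contain_cells:
                lo_c, hi_c = np.full(3, a), extent - a
                if np.any(hi_c <= lo_c):
                    raise RuntimeError("volume too small to contain cells of this size")
                center = rng.uniform(lo_c, hi_c)
            else:
                center = rng.uniform(np.zeros(3), extent)
            dist_cap = np.nan
            if cap is not None:
                dist_cap = _point_segment_distance(center, cap_p0, cap_p1) - cap.radius_um
                if config.size_distance_beta != 0.0:
                    factor = float(np.clip(
                        1.0 - config.size_distance_beta * dist_cap / d_ref, 0.2, 2.0))
                    a *= factor
            semi = np.array([a, a / aspect, a / aspect])
            axis = sample_axis(model, rng, center_um=center, aimed=aimed)
            R = _frame(axis)
            if _placement_ok(center, semi, R, placed, cap, cap_p0, cap_p1, margin):
                break
        else:
            raise RuntimeError(
                f"could not place cell {cell_id} after {config.max_attempts} attempts; "
                "use fewer n_cells or larger dims"
            )
        placed.append((center, semi, R))
        rows.append({
            "cell_id": cell_id, "cx_um": center[0], "cy_um": center[1], "cz_um": center[2],
            "a_um": semi[0], "b_um": semi[1], "c_um": semi[2],
            "ax": axis[0], "ay": axis[1], "az": axis[2],
            "polarized": bool(aimed),
            "distance_to_capillary_um": dist_cap,
        })

    # rasterize cells, then nuclei, then mitochondria (later stages paint on
    # top of the parent compartment only, so containment holds by construction)
    nucleus_scale = config.nucleus_volume_fraction ** (1.0 / 3.0)
    mito_counter = 0
    lo_m, hi_m = config.mito_per_cell
    nominal_aspect = float(np.mean(config.aspect_ratio_range))
    nominal_volume = (4.0 / 3.0) * np.pi * config.cell_radius_mean_um ** 3 / nominal_aspect ** 2
    for row, (center, semi, R) in zip(rows, placed):
        cell_id = row["cell_id"]
        lo, hi = _bbox_indices(center, np.full(3, semi[0]), dims, spacing_um)
        if np.any(hi <= lo):
            logger.warning("cell %d lies entirely outside the volume", cell_id)
            row["n_mito"] = 0
            continue
        inside = _inside_ellipsoid(center, semi, R, lo, hi, spacing_um)
        _paint(labels, inside, lo, hi, cell_id, only_on=0)
        records.append(SegmentRecord(cell_id, "cell"))

        nuc_id = NUCLEUS_ID_OFFSET + cell_id
        inside_nuc = _inside_ellipsoid(center, semi * nucleus_scale, R, lo, hi, spacing_um)
        _paint(labels, inside_nuc, lo, hi, nuc_id, only_on=cell_id)
        records.append(SegmentRecord(nuc_id, "nucleus", parent_id=cell_id))

        if hi_m > 0:
            volume = (4.0 / 3.0) * np.pi * np.prod(semi)
            count = int(round(rng.uniform(lo_m, hi_m) * volume / nominal_volume))
            n_painted = 0
            for _ in range(count):
                mito_id = MITO_ID_OFFSET + mito_counter + n_painted + 1
                if _paint_mito(labels, rng, center, semi, R, nucleus_scale,
                               config.mito_radius_um, dims, spacing_um, cell_id, mito_id):
                    records.append(SegmentRecord(mito_id, "mitochondrion", parent_id=cell_id))
                    n_painted += 1
            mito_counter += n_painted
            row["n_mito"] = n_painted
        else:
            row["n_mito"] = 0

    truth_cells = pd.DataFrame(
        rows,
        columns=["cell_id", "cx_um", "cy_um", "cz_um", "a_um", "b_um", "c_um",
                 "ax", "ay", "az", "polarized", "distance_to_capillary_um", "n_mito"],
    )
    truth_cells["complete"] = _complete_flags(labels, truth_cells["cell_id"])

    truth = GroundTruth(cells=truth_cells)
    if isinstance(model, PlaneAligned):
        truth.plane_normal = _unit(np.array(model.normal, dtype=float))
    if isinstance(model, Hotspot):
        truth.hotspot_um = np.array(model.point_um, dtype=float)

    volume = LabelVolume(labels=labels, spacing=config.spacing)
    table = SegmentTable(records)
    # structures swallowed entirely by clipping would orphan their record
    present = set(int(v) for v in volume.label_ids())
    table = SegmentTable([r for r in table if r.label_id in present or r.parent_id in present])
    return SyntheticScene(labels=volume, segments=table, truth=truth, config=config)


def _complete_flags(labels: np.ndarray, cell_ids: Iterable[int]) -> list[bool]:
    on_faces: set[int] = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            on_faces.update(np.unique(labels[tuple(sl)]).tolist())
    out = []
    for cid in cell_ids:
        touches = cid in on_faces or (NUCLEUS_ID_OFFSET + cid) in on_faces
        out.append(not touches and (labels == cid).any())
    return out


def _placement_ok(center, semi, R, placed, cap, cap_p0, cap_p1, margin) -> bool:
    for (c2, s2, R2) in placed:
        u = center - c2
        d = float(np.linalg.norm(u))
        if d < 1e-9:
            return False
        u /= d
        if d < _ellipsoid_support(semi, R, u) + _ellipsoid_support(s2, R2, u) + margin:
            return False
    if cap is not None:
        d_axis = _point_segment_distance(center, cap_p0, cap_p1)
        if d_axis < semi[0] + cap.radius_um + margin:
            return False
    return True


def _rasterize_capillary(labels, p0, p1, radius_um, spacing_um) -> None:
    dims = labels.shape
    lo = np.floor((np.minimum(p0, p1) - radius_um) / spacing_um - 1).astype(int)
    hi = np.ceil((np.maximum(p0, p1) + radius_um) / spacing_um + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(dims))
    xs = (np.arange(lo[0], hi[0]) + 0.5) * spacing_um[0]
    ys = (np.arange(lo[1], hi[1]) + 0.5) * spacing_um[1]
    zs = (np.arange(lo[2], hi[2]) + 0.5) * spacing_um[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    ab = p1 - p0
    t = np.clip(np.tensordot(P - p0, ab, axes=([-1], [0])) / np.dot(ab, ab), 0.0, 1.0)
    closest = p0 + t[..., None] * ab
    d = np.linalg.norm(P - closest, axis=-1)
    _paint(labels, d <= radius_um, lo, hi, CAPILLARY_ID, only_on=0)


def _paint_mito(labels, rng, center, semi, R, nucleus_scale, mito_radius_um,
                dims, spacing_um, cell_id, mito_id) -> bool:
    """Place one spherical mitochondrion in the cytoplasmic shell; True if painted."""
    pad = mito_radius_um / float(np.min(semi))
    rho_lo, rho_hi = nucleus_scale + pad, 1.0 - pad
    if rho_hi <= rho_lo:
        rho_lo, rho_hi = nucleus_scale, 1.0
    u = _unit(rng.standard_normal(3))
    rho = rng.uniform(rho_lo, rho_hi)
    p = center + R @ (rho * semi * u)
    lo, hi = _bbox_indices(p, np.full(3, mito_radius_um), dims, spacing_um)
    if np.any(hi <= lo):
        return False
    inside = _inside_ellipsoid(p, np.full(3, mito_radius_um), np.eye(3), lo, hi, spacing_um)
    box = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    target = inside & (box == cell_id)  # cytoplasm only: nucleus already painted
    if not target.any():
        return False
    box[target] = mito_id
    return True


def check_scene_invariants(scene: SyntheticScene) -> None:
    """Voxel-wise containment/disjointness checks; raises AssertionError on violation."""
    labels = scene.labels.labels
    for _, row in scene.truth.cells.iterrows():
        cid = int(row["cell_id"])
        center = row[["cx_um", "cy_um", "cz_um"]].to_numpy(dtype=float)
        semi = row[["a_um", "b_um", "c_um"]].to_numpy(dtype=float)
        R = _frame(row[["ax", "ay", "az"]].to_numpy(dtype=float))
        nuc_id = NUCLEUS_ID_OFFSET + cid
        child_ids = [nuc_id] + scene.segments.children_of(cid, "mitochondrion") if cid in scene.segments else []
        body = np.isin(labels, [cid] + child_ids)
        idx = np.argwhere(body)
        if idx.size == 0:
            continue
        pos = (idx + 0.5) * scene.config.spacing.as_um
        y = (pos - center) @ R
        q = np.sum((y / semi) ** 2, axis=1)
        assert np.all(q <= 1.0 + 1e-6), f"cell {cid}: voxels outside its true ellipsoid"
    # capillary disjointness and cell-cell disjointness hold by construction of
    # the label grid (one id per voxel); verify nucleus voxels never leak out
    nuc = (labels >= NUCLEUS_ID_OFFSET) & (labels < MITO_ID_OFFSET)
    assert not np.any(nuc & (labels == CAPILLARY_ID))


# ---------------------------------------------------------------------------
# EM-like rendering and sparse annotation
# ---------------------------------------------------------------------------

#: base grey level per structure class (8-bit-ish scale, separable by design)
CLASS_GREY = {
    "background": 60.0,
    "cell": 140.0,       # cytoplasm
    "nucleus": 110.0,
    "mitochondrion": 200.0,
    "capillary": 40.0,
    "immune_cell": 150.0,
    "red_blood_cell": 220.0,
}
TEXTURE_AMPLITUDE = 12.0
TEXTURE_SIGMA_PX = (3.0, 3.0, 1.0)


def render_em_like(
    scene: SyntheticScene,
    noise_sd: float = 8.0,
    jitter_px: int = 0,
    seed: int = 0,
) -> IntensityStack:
    """Render an EM-like grayscale stack from a synthetic scene.

    Per-class base grey levels, a smooth within-cell texture field, additive
    Gaussian noise, and optional per-slice integer translation jitter (to
    exercise flow estimation).  Jitter offsets are recorded in
    ``scene.truth.jitter``.  The rendering is a geometric phantom only — no
    membranes, stain physics or charging artefacts.
    """
    rng = np.random.default_rng(seed)
    labels = scene.labels.labels
    max_id = int(labels.max()) if labels.size else 0
    lut = np.full(max_id + 1, CLASS_GREY["background"], dtype=np.float32)
    for rec in scene.segments:
        if rec.label_id <= max_id:
            lut[rec.label_id] = CLASS_GREY[rec.segment_class]
    img = lut[labels]

    if TEXTURE_AMPLITUDE > 0:
        # texture lives inside cell bodies only (cytoplasm, nucleus, mitochondria)
        textured = np.zeros(max_id + 1, dtype=bool)
        for rec in scene.segments:
            if rec.label_id <= max_id:
                textured[rec.label_id] = rec.segment_class in (
                    "cell", "nucleus", "mitochondrion")
        texture = gaussian_filter(rng.standard_normal(labels.shape).astype(np.float32),
                                  TEXTURE_SIGMA_PX)
        texture *= TEXTURE_AMPLITUDE / max(float(texture.std()), 1e-9)
        img = img + texture * textured[labels]

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=labels.shape).astype(np.float32)

    offsets = np.zeros((labels.shape[2], 2), dtype=int)
    if jitter_px > 0:
        offsets[1:] = rng.integers(-jitter_px, jitter_px + 1, size=(labels.shape[2] - 1, 2))
        for iz in range(1, labels.shape[2]):
            img[:, :, iz] = np.roll(img[:, :, iz], tuple(offsets[iz]), axis=(0, 1))
    scene.truth.jitter = pd.DataFrame(
        {"iz": np.arange(labels.shape[2]), "jx": offsets[:, 0], "jy": offsets[:, 1]}
    )
    return IntensityStack(values=img.astype(np.float32), spacing=scene.labels.spacing)


def sparse_annotation(labels: LabelVolume, stride: int = 10) -> LabelVolume:
    """Keep labels only on every ``stride``-th section (iz = 0, stride, 2*stride, ...).

    Emulates manual annotation of 1 section out of ``stride`` (the workflow
    segments 1 image out of 10); all other sections are cleared to background.
    """
    if stride < 2:
        raise ValueError("stride must be >= 2")
    sparse = np.zeros_like(labels.labels)
    sparse[:, :, ::stride] = labels.labels[:, :, ::stride]
    return LabelVolume(labels=sparse, spacing=labels.spacing)


def translating_disk_stack(
    shape: tuple[int, int] = (96, 96),
    n_slices: int = 31,
    velocity_px: tuple[int, int] = (1, 0),
    radius_px: float = 18.0,
    start_px: tuple[float, float] | None = None,
    spacing: VoxelSpacing = VoxelSpacing(150.0, 150.0, 300.0),
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[IntensityStack, LabelVolume]:
    """A textured disk translating by an integer offset per section.

    Returns the rendered stack and the dense ground-truth label volume
    (disk = label 1): the standard moving-object phantom for testing
    flow-based label propagation.
    """
    rng = np.random.default_rng(seed)
    nx, ny = shape
    if start_px is None:
        start_px = (nx / 2 - velocity_px[0] * n_slices / 2,
                    ny / 2 - velocity_px[1] * n_slices / 2)
    bg_tex = gaussian_filter(rng.standard_normal((nx, ny)).astype(np.float32), 2.0) * 10.0
    disk_tex = gaussian_filter(rng.standard_normal((nx, ny)).astype(np.float32), 2.0) * 15.0
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    img = np.empty((nx, ny, n_slices), dtype=np.float32)
    lab = np.zeros((nx, ny, n_slices), dtype=np.int32)
    for iz in range(n_slices):
        cx = start_px[0] + velocity_px[0] * iz
        cy = start_px[1] + velocity_px[1] * iz
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= radius_px ** 2
        tex = np.roll(disk_tex, (int(round(cx)), int(round(cy))), axis=(0, 1))
        sl = 60.0 + bg_tex
        sl = np.where(mask, 150.0 + tex, sl)
        if noise_sd > 0:
            sl = sl + rng.normal(0.0, noise_sd, size=(nx, ny)).astype(np.float32)
        img[:, :, iz] = sl
        lab[:, :, iz][mask] = 1
    return (IntensityStack(values=img, spacing=spacing),
            LabelVolume(labels=lab, spacing=spacing))
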