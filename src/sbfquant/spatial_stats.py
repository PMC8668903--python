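"""Capillary-distance analysis, Spearman correlations and the per-cell report.

Distances are exact anisotropic Euclidean distances between voxel centres
(µm).  A structure's primary distance to the capillary is the minimum of the
distance map over its voxels (surface-to-surface proximity); the distance at
the structure's centroid is kept as a secondary, more size-insensitive
measure.  Monotone associations are tested with Spearman's rank correlation
(mid-ranks for ties; exact permutation p-value for n <= 9, t-approximation
otherwise), significant at p < 0.05 with no multiplicity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata, t as t_dist

from .morphometry import cell_body_mask, compose_all
from .volume_model import LabelVolume, SegmentTable, VoxelSpacing

#: largest n for which the exact permutation null of rho is enumerated
EXACT_PERMUTATION_MAX_N = 9
ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    rho: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def capillary_distance_map(capillary_mask: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    """Exact anisotropic Euclidean distance (µm) to the nearest capillary voxel.

    Zero on capillary voxels; 1-Lipschitz with respect to the physical step
    between voxel centres.
    """
    if not capillary_mask.any():
        raise ValueError("empty capillary mask")
    return ndimage.distance_transform_edt(~capillary_mask, sampling=spacing.as_um)


def structure_distance(mask: np.ndarray, dmap: np.ndarray) -> float:
    """Minimum capillary distance over a structure's voxels (µm)."""
    if not mask.any():
        raise ValueError("empty structure mask")
    d = float(dmap[mask].min())
    if d == 0.0:
        warnings.warn("structure overlaps the capillary support (distance 0)", stacklevel=2)
    return d


def centroid_distance(mask: np.ndarray, dmap: np.ndarray, spacing: VoxelSpacing) -> float:
    """Capillary distance interpolated at the structure's centroid (µm)."""
    if not mask.any():
        raise ValueError("empty structure mask")
    centroid_idx = np.argwhere(mask).mean(axis=0)  # distance map is indexed per voxel
    return float(ndimage.map_coordinates(dmap, centroid_idx[:, None], order=1, mode="nearest")[0])


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Spearman rank correlation with mid-ranks and a two-sided p-value.

    For n <= 9 the p-value is exact: the permutation distribution of rho over
    all n! orderings is enumerated.  For larger n the usual t-approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 degrees of freedom is
    used (this differs slightly from spreadsheet/Prism conventions at small
    n; the exact branch covers those).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    rx = rankdata(x)  # mid-ranks for ties
    ry = rankdata(y)
    rho = _pearson(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, n)
    return CorrelationResult(x_name=x_name, y_name=y_name, n=n, rho=rho, p_value=p)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / math.sqrt(np.dot(a, a) * np.dot(b, b)))


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    perms = np.array(list(permutations(ry)))
    a = rx - rx.mean()
    b = perms - ry.mean()
    num = b @ a
    denom = math.sqrt(np.dot(a, a) * np.dot(ry - ry.mean(), ry - ry.mean()))
    rhos = num / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * t_dist.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

VOLUME_COLUMNS = {
    "cell": "cell_volume_um3",
    "cytoplasm": "cytoplasm_volume_um3",
    "nucleus": "nucleus_volume_um3",
    "mitochondria": "mito_total_volume_um3",
}


def cell_table(
    labels: LabelVolume,
    segments: SegmentTable,
    plane=None,
    polarized_ids: set[int] | None = None,
) -> pd.DataFrame:
    """Per-cell joined table: composition, capillary distances, inclination, polarity."""
    table = compose_all(labels, segments)
    cap_ids = segments.ids_of_class("capillary")
    if cap_ids and len(table):
        cap_mask = np.isin(labels.labels, cap_ids)
        dmap = capillary_distance_map(cap_mask, labels.spacing)
        dmin, dcen = [], []
        for cid in table["cell_id"]:
            mask = cell_body_mask(labels, segments, int(cid))
            dmin.append(structure_distance(mask, dmap))
            dcen.append(centroid_distance(mask, dmap, labels.spacing))
        table["distance_to_capillary_um"] = dmin
        table["centroid_distance_um"] = dcen
    else:
        table["distance_to_capillary_um"] = np.nan
        table["centroid_distance_um"] = np.nan
    if plane is not None:
        table["inclination_deg"] = [
            plane.inclinations_deg.get(int(cid), np.nan) for cid in table["cell_id"]
        ]
    else:
        table["inclination_deg"] = np.nan
    table["polarized"] = [
        int(cid) in (polarized_ids or set()) for cid in table["cell_id"]
    ]
    return table


def build_report(cells: pd.DataFrame) -> pd.DataFrame:
    """Correlation summary over a per-cell table (see :func:`cell_table`).

    Computes the six volume-volume Spearman correlations over (cell,
    cytoplasm, nucleus, mitochondria) and — when capillary distances are
    present — the five distance correlations against the four component
    volumes and the nucleocytoplasmic ratio.
    """
    results: list[CorrelationResult] = []
    names = list(VOLUME_COLUMNS)
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            results.append(
                spearman(cells[VOLUME_COLUMNS[ni]], cells[VOLUME_COLUMNS[nj]],
                         x_name=f"{ni}_volume", y_name=f"{nj}_volume")
            )
    if cells["distance_to_capillary_um"].notna().all():
        dist = cells["distance_to_capillary_um"]
        for ni in names:
            results.append(
                spearman(dist, cells[VOLUME_COLUMNS[ni]],
                         x_name="distance_to_capillary", y_name=f"{ni}_volume")
            )
        results.append(
            spearman(dist, cells["nucleocytoplasmic_ratio"],
                     x_name="distance_to_capillary", y_name="nucleocytoplasmic_ratio")
        )
    return pd.DataFrame(
        [
            {"x": r.x_name, "y": r.y_name, "n": r.n, "rho": r.rho,
             "p_value": r.p_value, "significant": r.significant}
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# figures (optional convenience)
# ---------------------------------------------------------------------------


def plot_report(cells: pd.DataFrame, histogram=None, out_path=None):
    """Scatter panels of the distance correlations plus the inclination histogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    panels = list(VOLUME_COLUMNS.items()) + [("NC ratio", "nucleocytoplasmic_ratio")]
    for ax, (name, col) in zip(axes.flat, panels):
        ax.scatter(cells["distance_to_capillary_um"], cells[col], s=14)
        ax.set_xlabel("distance to capillary (µm)")
        ax.set_ylabel(name)
    last = axes.flat[-1]
    if histogram is not None:
        last.bar(histogram.bin_edges_deg[:-1], histogram.counts, width=9, align="edge")
        last.set_xlabel("inclination (deg)")
        last.set_ylabel("cells")
    else:
        last.axis("off")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
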