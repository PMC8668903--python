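"""Semi-automatic segmentation by optical-flow label propagation.

Structures in a block-face stack drift only slightly between consecutive
sections, so a dense segmentation can be obtained from annotations on every
k-th section: estimate the 2D displacement field between neighbouring EM
sections (coarse-to-fine variational TV-L1 flow) and warp the labels of the
nearest annotated section, slice by slice, onto the unannotated ones.

Conventions: a :class:`FlowField` ``u`` for an ordered pair (source →
target) satisfies ``target(p) ≈ source(p - u(p))``; label warping samples
nearest-neighbour (labels are categorical) and out-of-bounds samples become
background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.registration import optical_flow_tvl1

from .volume_model import IntensityStack, LabelVolume


@dataclass
class FlowParams:
    """Parameters of the variational flow and of the propagation schedule.

    ``smoothness_weight`` is the coupling weight of the TV-L1 energy
    (balance between the data term and the smoothness of the field);
    ``pyramid_levels`` is informational — the solver builds its own
    coarse-to-fine pyramid down to a fixed minimum size.  ``stride`` is the
    annotation period along z (1 section out of ``stride`` is annotated).
    """

    smoothness_weight: float = 15.0
    pyramid_levels: int = 3
    warp_iterations: int = 5
    stride: int = 10

    def __post_init__(self) -> None:
        if min(self.smoothness_weight, self.pyramid_levels, self.warp_iterations, self.stride) <= 0:
            raise ValueError("all FlowParams fields must be positive")


@dataclass
class FlowField:
    """Dense per-pixel displacement (ux, uy) for an ordered slice pair."""

    ux: np.ndarray
    uy: np.ndarray

    def __post_init__(self) -> None:
        if self.ux.shape != self.uy.shape or self.ux.ndim != 2:
            raise ValueError("flow components must be 2D arrays of equal shape")
        if not (np.isfinite(self.ux).all() and np.isfinite(self.uy).all()):
            raise ValueError("flow field contains non-finite values")

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "FlowField":
        return cls(np.zeros(shape), np.zeros(shape))


def estimate_flow(source: np.ndarray, target: np.ndarray,
                  params: FlowParams = FlowParams()) -> FlowField:
    """Estimate the dense displacement carrying ``source`` onto ``target``.

    Deterministic for fixed inputs and parameters.  Constant (feature-free)
    image pairs yield zero flow with a warning.
    """
    source = np.asarray(source, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    if source.shape != target.shape:
        raise ValueError(f"slice shapes differ: {source.shape} vs {target.shape}")
    if source.ndim != 2 or min(source.shape) < 16:
        raise ValueError("slices must be 2D and at least 16x16 px")
    if np.ptp(source) == 0 and np.ptp(target) == 0:
        warnings.warn("constant images: returning zero flow", stacklevel=2)
        return FlowField.zero(source.shape)
    # solver convention: reference(p) ≈ moving(p + v(p)); with reference=target,
    # moving=source this gives target(p) ≈ source(p + v(p)), hence u = -v
    # median prefiltering of the warped image stabilises the flow near label
    # boundaries (the standard outlier-removal step of improved TV-L1)
    v = optical_flow_tvl1(
        target, source,
        attachment=params.smoothness_weight,
        num_warp=params.warp_iterations,
        prefilter=True,
    )
    return FlowField(ux=-v[0], uy=-v[1])


def warp_labels(labels: np.ndarray, flow: FlowField) -> np.ndarray:
    """Warp a 2D label slice along a flow field, nearest-neighbour.

    ``out(p) = labels(p - u(p))`` with out-of-bounds samples set to
    background (0).
    """
    if labels.shape != flow.ux.shape:
        raise ValueError(f"label shape {labels.shape} does not match flow {flow.ux.shape}")
    nx, ny = labels.shape
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sx = np.rint(X - flow.ux).astype(np.int64)
    sy = np.rint(Y - flow.uy).astype(np.int64)
    valid = (sx >= 0) & (sx < nx) & (sy >= 0) & (sy < ny)
    out = np.zeros_like(labels)
    out[valid] = labels[sx[valid], sy[valid]]
    return out


def nearest_annotated(nz: int, stride: int) -> np.ndarray:
    """Index of the annotated source section for every section.

    Annotated sections sit at ``iz ≡ 0 (mod stride)``.  Each section maps to
    its nearest annotated one; exact ties go to the lower index.
    """
    iz = np.arange(nz)
    lower = (iz // stride) * stride
    upper = lower + stride
    upper = np.minimum(upper, ((nz - 1) // stride) * stride)
    upper = np.maximum(upper, lower)
    pick_upper = (upper - iz) < (iz - lower)  # strict: ties -> lower
    return np.where(pick_upper, upper, lower)


def propagate_stack(sparse: LabelVolume, stack: IntensityStack,
                    params: FlowParams = FlowParams()) -> LabelVolume:
    """Propagate sparse per-section annotations through the whole stack.

    Every unannotated section receives the labels of its nearest annotated
    section, warped sequentially through the chain of section-to-section
    flows (EM content decorrelates quickly along z, so long-range flow is
    never estimated directly).  Annotated sections are preserved verbatim.
    The output label-id set is always a subset of the input's.
    """
    if sparse.dims != stack.dims:
        raise ValueError(f"label dims {sparse.dims} do not match stack dims {stack.dims}")
    if not sparse.labels.any():
        raise ValueError("no annotated slices: sparse volume is empty")
    nz = stack.nz
    source_of = nearest_annotated(nz, params.stride)
    out = np.zeros_like(sparse.labels)
    out[:, :, ::params.stride] = sparse.labels[:, :, ::params.stride]

    for a in range(0, nz, params.stride):
        # forward chain a -> a+1 -> ...
        current = sparse.labels[:, :, a]
        for iz in range(a + 1, nz):
            if source_of[iz] != a:
                break
            fl = estimate_flow(stack.slice(iz - 1), stack.slice(iz), params)
            current = warp_labels(current, fl)
            out[:, :, iz] = current
        # backward chain a -> a-1 -> ...
        current = sparse.labels[:, :, a]
        for iz in range(a - 1, -1, -1):
            if source_of[iz] != a:
                break
            fl = estimate_flow(stack.slice(iz + 1), stack.slice(iz), params)
            current = warp_labels(current, fl)
            out[:, :, iz] = current
    return LabelVolume(labels=out, spacing=sparse.spacing)
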