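"""Stack pre-processing: cropping and slice-wise normalization to 8 bit.

Block-face acquisitions drift in brightness/contrast from section to section,
so normalization is strictly per slice: each section is z-scored against its
own mean and standard deviation, clipped, and mapped affinely onto [0, 255].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume_model import IntensityStack


@dataclass(frozen=True)
class NormalizationParams:
    """Slice-wise z-scoring parameters.

    ``clip_sigmas`` bounds the z-scores at ±clip_sigmas before the 8-bit map,
    making the output robust to hot pixels; 3 sigma keeps >99% of a Gaussian
    slice's dynamic range.
    """

    clip_sigmas: float = 3.0

    def __post_init__(self) -> None:
        if not self.clip_sigmas > 0:
            raise ValueError("clip_sigmas must be > 0")


def crop_stack(stack: IntensityStack, roi: tuple[int, int, int, int]) -> IntensityStack:
    """Crop every section to the half-open pixel rectangle ``(x0, x1, y0, y1)``."""
    x0, x1, y0, y1 = roi
    nx, ny, _ = stack.dims
    if not (0 <= x0 <= x1 <= nx and 0 <= y0 <= y1 <= ny):
        raise ValueError(f"roi {roi} out of bounds for dims {stack.dims}")
    if x0 == x1 or y0 == y1:
        raise ValueError("empty ROI")
    return IntensityStack(values=stack.values[x0:x1, y0:y1, :].copy(), spacing=stack.spacing)


def normalize_slices(
    stack: IntensityStack, params: NormalizationParams = NormalizationParams()
) -> IntensityStack:
    """Slice-wise z-score, clip at ±clip_sigmas and map to 8-bit.

    Per section: ``z = (v - mean) / sd`` (population sd), clipped to
    ``±clip_sigmas`` and mapped affinely to [0, 255], rounded to nearest with
    ties away from zero; a pixel at the slice mean therefore maps to 128.
    A constant section (sd = 0) maps entirely to 128 with a warning.
    """
    c = params.clip_sigmas
    out = np.empty(stack.dims, dtype=np.uint8)
    for iz in range(stack.nz):
        sl = stack.values[:, :, iz].astype(np.float64)
        mu = sl.mean()
        sd = sl.std()  # population convention (divide by N)
        if sd == 0:
            warnings.warn(f"slice {iz} is constant; normalized to mid-grey", stacklevel=2)
            out[:, :, iz] = 128
            continue
        z = np.clip((sl - mu) / sd, -c, c)
        scaled = (z + c) / (2 * c) * 255.0
        out[:, :, iz] = np.floor(scaled + 0.5).astype(np.uint8)  # ties away from zero
    return IntensityStack(values=out, spacing=stack.spacing)
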