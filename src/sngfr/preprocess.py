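"""Z-stack cleanup: 3D median denoising and spectral bleedthrough removal.

The filtered-dye channel of a multiphoton z-stack is contaminated by emission
from the vessel and nuclear dyes (spectral bleedthrough). Cleanup is a 3D
median filter followed by voxel-wise subtraction of the contaminant channels,
clamped at zero — the order (filter, then subtract) matters because the median
is nonlinear.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["median_filter_3d", "subtract_bleedthrough", "clean_dye_channel"]


def median_filter_3d(volume: np.ndarray, radius: int | tuple[int, int, int] = 1) -> np.ndarray:
    """Median-filter a (z, y, x) volume with a (2r+1)³ box neighborhood.

    Borders are handled by edge replication. ``radius`` may be a single int or
    a per-axis triple; radius 0 is the identity.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    if np.isscalar(radius):
        radius = (int(radius),) * 3
    radius = tuple(int(r) for r in radius)
    if any(r < 0 for r in radius):
        raise ValueError(f"radius must be non-negative per axis, got {radius}")
    if any(2 * r + 1 > s for r, s in zip(radius, volume.shape)):
        raise ValueError(f"kernel {radius} exceeds volume extent {volume.shape}")
    if all(r == 0 for r in radius):
        return volume.copy()
    size = tuple(2 * r + 1 for r in radius)
    return ndimage.median_filter(volume, size=size, mode="nearest")


def subtract_bleedthrough(
    target: np.ndarray,
    contaminants: Sequence[np.ndarray],
    scales: Sequence[float] | float = 1.0,
) -> np.ndarray:
    """Remove contaminant channels from the target channel, voxel-wise.

    ``out = max(0, target − Σ scaleᵢ · contaminantᵢ)``. The default scale of
    1.0 per contaminant mirrors plain channel subtraction; the clamp at zero
    matches unsigned-integer subtraction semantics and keeps downstream
    thresholds meaningful.
    """
    target = np.asarray(target, dtype=float)
    contaminants = [np.asarray(c, dtype=float) for c in contaminants]
    if np.isscalar(scales):
        scales = [float(scales)] * len(contaminants)
    scales = [float(s) for s in scales]
    if len(scales) != len(contaminants):
        raise ValueError("one scale per contaminant channel required")
    if any(s < 0 for s in scales):
        raise ValueError(f"scales must be non-negative, got {scales}")
    for i, c in enumerate(contaminants):
        if c.shape != target.shape:
            raise ValueError(
                f"contaminant {i} shape {c.shape} does not match target {target.shape}"
            )
    out = target.copy()
    for s, c in zip(scales, contaminants):
        out -= s * c
    np.maximum(out, 0.0, out=out)
    return out


def clean_dye_channel(
    dye: np.ndarray,
    contaminants: Sequence[np.ndarray],
    median_radius: int = 1,
    scales: Sequence[float] | float = 1.0,
) -> np.ndarray:
    """Full cleanup: median-filter every channel, then subtract contaminants."""
    dye_f = median_filter_3d(dye, median_radius)
    cont_f = [median_filter_3d(c, median_radius) for c in contaminants]
    return subtract_bleedthrough(dye_f, cont_f, scales)
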