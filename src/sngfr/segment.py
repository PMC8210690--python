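"""Proximal-tubule segmentation: thresholding, seeded 3D watershed, ROI-guided selection.

The cleaned dye channel is binarized (Otsu by default), partitioned into
basins by a watershed on the negated Euclidean distance transform seeded from
distance-transform maxima, and the basins whose x-y projection touches the
user-drawn tubule ROI are united into the tubule mask. A long tubule is often
split into several basins by the watershed; the ROI decides which fragments
belong to the proximal tubule, which is why selection takes a union rather
than a single best label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed

from .io import AcquisitionMeta, PolylineROI, write_volume

__all__ = ["LabelVolume", "TubuleMask", "binarize", "watershed_3d", "select_tubule_label"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class LabelVolume:
    """Watershed labels (0 = background) over a (z, y, x) volume."""

    labels: np.ndarray
    voxel_dims: tuple[float, float, float]  # (z, y, x) µm

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z, y, x)")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class TubuleMask:
    """Boolean mask of the selected tubule with its physical voxel size."""

    mask: np.ndarray
    voxel_dims: tuple[float, float, float]  # (z, y, x) µm

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        if not self.mask.any():
            raise ValueError("tubule mask is empty")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_dims))

    @property
    def volume_um3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_um3

    def is_connected(self) -> bool:
        _, n = ndimage.label(self.mask, structure=_STRUCT_26)
        return n == 1


def binarize(
    volume: np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> tuple[np.ndarray, float]:
    """Binarize a volume; foreground = voxels ≥ threshold.

    Returns ``(mask, threshold)`` so the threshold can be logged. ``method``
    is ``"otsu"`` (requires a non-constant volume) or ``"fixed"`` (requires
    ``fixed_value``).
    """
    volume = np.asarray(volume)
    if method == "otsu":
        if volume.max() == volume.min():
            raise ValueError("cannot Otsu-threshold a constant volume")
        t = float(threshold_otsu(volume))
        # Otsu's optimal split is {x ≤ t} vs {x > t}; our foreground rule is
        # x ≥ threshold, so report the smallest data value strictly above t
        above = volume[volume > t]
        thr = float(above.min()) if above.size else t
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("method 'fixed' requires fixed_value")
        thr = float(fixed_value)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return volume >= thr, thr


def watershed_3d(
    volume: np.ndarray,
    foreground: np.ndarray,
    voxel_dims: tuple[float, float, float],
    seed_min_distance: int = 5,
) -> LabelVolume:
    """Partition the foreground into basins via distance-transform-seeded watershed.

    Seeds are local maxima of the Euclidean distance transform of the
    foreground, at least ``seed_min_distance`` voxels apart; the watershed
    floods the negated distance transform restricted to the foreground.
    Background keeps label 0.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if not foreground.any():
        raise ValueError("foreground is empty; nothing to segment")
    dist = ndimage.distance_transform_edt(foreground)
    seed_coords = peak_local_max(
        dist, min_distance=int(seed_min_distance), labels=foreground, exclude_border=False
    )
    markers = np.zeros(foreground.shape, dtype=np.int32)
    for i, (z, y, x) in enumerate(seed_coords, start=1):
        markers[z, y, x] = i
    if markers.max() == 0:  # degenerate: tiny foreground with no distinct peak
        markers[tuple(np.argwhere(foreground)[0])] = 1
    labels = watershed(-dist, markers=markers, mask=foreground)
    # small components can end up seedless (peak suppression): label them too,
    # so the basins plus background always partition the volume
    orphan = foreground & (labels == 0)
    if orphan.any():
        comp, _ = ndimage.label(orphan, structure=_STRUCT_26)
        labels = np.where(orphan, comp + labels.max(), labels)
    return LabelVolume(labels.astype(np.int32), voxel_dims)


def select_tubule_label(
    labels: LabelVolume,
    roi: PolylineROI,
    dilation_px: int = 3,
    save_path: str | Path | None = None,
) -> TubuleMask:
    """Unite the watershed labels whose x-y projection touches the (dilated) ROI.

    The dilation (default 3 px) absorbs small ROI placement error. If
    ``save_path`` is given, the selected mask is written as a uint16 TIFF for
    visual verification.
    """
    lab = labels.labels
    if lab.max() == 0:
        raise ValueError("label volume contains no objects")
    h, w = lab.shape[1], lab.shape[2]
    roi_mask = _rasterize_polyline(roi, (h, w))
    if dilation_px > 0:
        roi_mask = ndimage.binary_dilation(roi_mask, structure=disk(int(dilation_px)))
    # test per voxel across z so a label hidden behind another in projection still counts
    hit = np.unique(lab[:, roi_mask]) if roi_mask.any() else np.array([], dtype=int)
    hit = hit[hit > 0]
    if hit.size == 0:
        raise ValueError("ROI does not touch any segmented object")
    mask = np.isin(lab, hit)
    tubule = TubuleMask(mask, labels.voxel_dims)
    if save_path is not None:
        write_volume(mask.astype(np.uint16), save_path)
    return tubule


def _rasterize_polyline(roi: PolylineROI, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the polyline into a boolean (y, x) mask, clipped to ``shape``."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    verts = np.rint(roi.vertices).astype(int)
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True
    return mask
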