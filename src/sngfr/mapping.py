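"""Mapping the tubule onto an arclength axis: kymograph and cumulative-volume profile.

Two coordinate transforms connect the raw data to the flow estimate:

1. The polyline ROI becomes a regular arclength grid (µm from the glomerular
   end); sampling every frame of the time series on that grid yields the
   kymograph (position × time intensity map).
2. Every voxel of the segmented tubule mask is assigned the arclength of the
   orthogonal projection of its (x, y) center onto the polyline (z is ignored
   for the assignment: the time series is a single plane while the volume is
   3D, and projecting in x-y is the only correspondence that uses the ROI as
   drawn). Counting voxels by assigned arclength gives the monotone map from
   position to cumulative tubule volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import AcquisitionMeta, FrameSeries, PolylineROI
from .segment import TubuleMask

__all__ = [
    "ArclengthGrid",
    "Kymograph",
    "VolumeProfile",
    "arclength_grid",
    "sample_profile",
    "build_kymograph",
    "project_points_to_polyline",
    "map_cumulative_volume",
]


@dataclass
class ArclengthGrid:
    """Regular sample points along the ROI.

    ``positions_um`` runs from 0 at the glomerular end; ``points_px`` are the
    corresponding (x, y) pixel coordinates and ``tangents`` unit tangent
    vectors (for width-averaged sampling). ``length_um`` is the full ROI
    arclength, the single source of truth for the reported tubule length.
    """

    positions_um: np.ndarray
    points_px: np.ndarray  # (n, 2) (x, y)
    tangents: np.ndarray  # (n, 2) unit vectors
    length_um: float


@dataclass
class Kymograph:
    """Dye intensity sampled along the tubule for every frame."""

    positions_um: np.ndarray  # (p,)
    values: np.ndarray  # (p, t)
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.positions_um.shape[0]:
            raise ValueError("values must have one row per position")
        d = np.diff(self.positions_um)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("positions must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kymograph values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            self.values, columns=[f"frame_{t}" for t in range(self.n_frames)]
        )
        df.insert(0, "position_um", self.positions_um)
        df.to_csv(path, index=False, float_format="%.10g")
        return path


@dataclass
class VolumeProfile:
    """Cumulative segmented tubule volume (µm³) versus arclength (µm)."""

    positions_um: np.ndarray
    cumvol_um3: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.cumvol_um3 = np.asarray(self.cumvol_um3, dtype=float)
        if self.positions_um.shape != self.cumvol_um3.shape:
            raise ValueError("positions and cumulative volumes must align")
        if np.any(np.diff(self.cumvol_um3) < 0):
            raise ValueError("cumulative volume must be non-decreasing")
        if self.cumvol_um3[0] < 0:
            raise ValueError("cumulative volume must be non-negative")

    @property
    def total_um3(self) -> float:
        return float(self.cumvol_um3[-1])

    def volume_at(self, position_um: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of cumulative volume at arbitrary arclength."""
        return np.interp(position_um, self.positions_um, self.cumvol_um3)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"position_um": self.positions_um, "cumvol_um3": self.cumvol_um3}
        ).to_csv(path, index=False, float_format="%.10g")
        return path


def arclength_grid(
    roi: PolylineROI, pixel_size_um: float, spacing_um: float | None = None
) -> ArclengthGrid:
    """Place sample points every ``spacing_um`` along the ROI.

    Default spacing is one pixel (no super-resolution pretense). Points are
    linearly interpolated along the polyline segments; the tangent at a point
    is the direction of the segment it lies on.
    """
    if spacing_um is None:
        spacing_um = pixel_size_um
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    verts = roi.vertices
    seg_vec = np.diff(verts, axis=0)
    seg_len_um = np.hypot(seg_vec[:, 0], seg_vec[:, 1]) * pixel_size_um
    cum = np.concatenate([[0.0], np.cumsum(seg_len_um)])
    length = float(cum[-1])
    if length <= 0:
        raise ValueError("degenerate ROI with zero length")
    n = int(np.floor(length / spacing_um + 1e-9)) + 1
    positions = np.arange(n) * spacing_um
    seg_idx = np.clip(np.searchsorted(cum, positions, side="right") - 1, 0, len(seg_len_um) - 1)
    frac = (positions - cum[seg_idx]) / seg_len_um[seg_idx]
    points = verts[seg_idx] + frac[:, None] * seg_vec[seg_idx]
    tangents = seg_vec[seg_idx] / np.hypot(*seg_vec[seg_idx].T)[:, None]
    return ArclengthGrid(positions, points, tangents, length)


def sample_profile(
    frame: np.ndarray,
    points_px: np.ndarray,
    line_width_px: int = 1,
    tangents: np.ndarray | None = None,
) -> np.ndarray:
    """Bilinearly sample a 2D frame at (x, y) points.

    With ``line_width_px > 1`` the value at each point is the mean over
    ``line_width_px`` single-pixel-spaced offsets perpendicular to the local
    tangent (which must then be supplied), mirroring a wide line ROI.
    """
    frame = np.asarray(frame, dtype=float)
    points_px = np.asarray(points_px, dtype=float)
    h, w = frame.shape
    if line_width_px < 1:
        raise ValueError("line_width_px must be ≥ 1")
    if line_width_px > 1:
        if tangents is None:
            raise ValueError("tangents required for line_width_px > 1")
        normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
        offsets = np.arange(line_width_px) - (line_width_px - 1) / 2.0
        stacks = [
            _bilinear(frame, points_px + o * normals, h, w) for o in offsets
        ]
        return np.mean(stacks, axis=0)
    return _bilinear(frame, points_px, h, w)


def _bilinear(frame: np.ndarray, pts: np.ndarray, h: int, w: int) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x < 0) or np.any(y < 0) or np.any(x > w - 1) or np.any(y > h - 1):
        raise ValueError("sample point outside frame bounds")
    return ndimage.map_coordinates(frame, [y, x], order=1, mode="nearest")


def build_kymograph(
    series: FrameSeries,
    roi: PolylineROI,
    spacing_um: float | None = None,
    line_width_px: int = 1,
) -> tuple[Kymograph, ArclengthGrid]:
    """Sample every frame along the ROI, producing the position × time map."""
    roi.check_bounds(series.frame_shape)
    grid = arclength_grid(roi, series.meta.pixel_size_um, spacing_um)
    values = np.empty((len(grid.positions_um), series.n_frames))
    for t in range(series.n_frames):
        values[:, t] = sample_profile(
            series.frames[t], grid.points_px, line_width_px, grid.tangents
        )
    return Kymograph(grid.positions_um, values, series.meta), grid


def project_points_to_polyline(
    points_px: np.ndarray, roi: PolylineROI, pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Arclength (µm) of the nearest orthogonal projection of each point.

    Returns ``(arclengths_um, distances_um)``. Ties between segments resolve
    to the smaller arclength, deterministically.
    """
    pts = np.asarray(points_px, dtype=float)
    verts = roi.vertices
    seg_vec = np.diff(verts, axis=0)  # (s, 2)
    seg_len2 = np.einsum("ij,ij->i", seg_vec, seg_vec)
    seg_len_um = np.sqrt(seg_len2) * pixel_size_um
    cum_um = np.concatenate([[0.0], np.cumsum(seg_len_um)])[:-1]

    rel = pts[:, None, :] - verts[None, :-1, :]  # (n, s, 2)
    t = np.einsum("nsj,sj->ns", rel, seg_vec) / seg_len2[None, :]
    t = np.clip(t, 0.0, 1.0)
    foot = verts[None, :-1, :] + t[..., None] * seg_vec[None, :, :]
    d2 = np.einsum("nsj->ns", (pts[:, None, :] - foot) ** 2)
    s_along = cum_um[None, :] + t * seg_len_um[None, :]

    min_d2 = d2.min(axis=1)
    tied = d2 <= min_d2[:, None] + 1e-12
    s_assigned = np.where(tied, s_along, np.inf).min(axis=1)
    return s_assigned, np.sqrt(min_d2) * pixel_size_um


def map_cumulative_volume(
    mask: TubuleMask,
    roi: PolylineROI,
    positions_um: np.ndarray,
    pixel_size_um: float,
) -> VolumeProfile:
    """Count mask voxels by projected arclength into a cumulative volume map.

    Voxels whose projection parameter falls strictly outside ``[0, L]`` — i.e.
    whose nearest foot point clamps to an ROI endpoint *and* that overhang the
    line — are excluded (end overhang). ``cumvol[i]`` is the voxel volume
    times the count of voxels assigned arclength ≤ ``positions_um[i]``.
    """
    zyx = np.argwhere(mask.mask)
    if zyx.size == 0:
        raise ValueError("empty tubule mask")
    pts_xy = zyx[:, [2, 1]].astype(float)  # voxel centers, (x, y)
    s, _d = project_points_to_polyline(pts_xy, roi, pixel_size_um)
    # endpoint-clamped voxels: recompute unclamped parameter on first/last segment
    verts = roi.vertices
    keep = _inside_span(pts_xy, verts, s, pixel_size_um)
    s = s[keep]
    if s.size == 0:
        raise ValueError("no tubule voxel projects inside the ROI span")
    counts = np.searchsorted(np.sort(s), np.asarray(positions_um), side="right")
    cumvol = counts * mask.voxel_volume_um3
    return VolumeProfile(np.asarray(positions_um, dtype=float), cumvol)


def _inside_span(
    pts_xy: np.ndarray, verts: np.ndarray, s_um: np.ndarray, pixel_size_um: float
) -> np.ndarray:
    """Voxels overhanging the ROI ends (unclamped parameter outside [0, L])."""
    first_vec = verts[1] - verts[0]
    t0 = (pts_xy - verts[0]) @ first_vec / (first_vec @ first_vec)
    last_vec = verts[-1] - verts[-2]
    t1 = (pts_xy - verts[-2]) @ last_vec / (last_vec @ last_vec)
    over_start = (s_um <= 0.0) & (t0 < 0.0)
    over_end = (t1 > 1.0) & (s_um >= _total(verts, pixel_size_um) - 1e-9)
    return ~(over_start | over_end)


def _total(verts: np.ndarray, pixel_size_um: float) -> float:
    d = np.diff(verts, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])) * pixel_size_um)
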