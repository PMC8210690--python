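"""Reading and writing of acquisition data: TIFF stacks, polyline ROIs, metadata, result tables.

Conventions used throughout the package (stated once, here):

* Pixel/voxel coordinates are 0-based; an ROI vertex ``(x, y)`` addresses the
  *center* of column ``x``, row ``y``. Readers never rescale by pixel size.
* Z-stacks are stored ``(z, y, x)``.
* Physical metadata (pixel size, voxel depth, frame rate) comes from a sidecar
  config, never from TIFF tags, which are unreliable across exporters.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "AcquisitionMeta",
    "FrameSeries",
    "ChannelVolumes",
    "PolylineROI",
    "ResultRow",
    "FormatError",
    "read_frame_series",
    "write_frame_series",
    "read_channel_volumes",
    "write_volume",
    "read_polyline_roi",
    "write_polyline_roi",
    "read_meta",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """Raised when an external file does not match its expected layout."""


# Default acquisition settings of the two-photon setup the workflow targets:
# 40x water-immersion objective, resonant time series.
DEFAULT_PIXEL_SIZE_UM = 0.8513
DEFAULT_VOXEL_DEPTH_UM = 1.0
DEFAULT_FRAME_RATE_FPS = 6.0


@dataclass(frozen=True)
class AcquisitionMeta:
    """Physical calibration of one acquisition.

    Parameters
    ----------
    pixel_size_um : float
        Lateral size of one pixel in x and y, micrometres.
    voxel_depth_um : float
        Z spacing of the z-stack, micrometres.
    frame_rate_fps : float
        Frame rate of the time series, frames per second.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    voxel_depth_um: float = DEFAULT_VOXEL_DEPTH_UM
    frame_rate_fps: float = DEFAULT_FRAME_RATE_FPS

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "voxel_depth_um", "frame_rate_fps"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and strictly positive, got {v!r}")

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.voxel_depth_um


@dataclass
class FrameSeries:
    """An ordered 2D+t single-channel intensity series (the filtered-dye channel)."""

    frames: np.ndarray  # (t, y, x)
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (t, y, x), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("at least 2 frames required")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class ChannelVolumes:
    """Co-registered 3D intensity rasters (z, y, x), one per detection channel."""

    channels: dict[str, np.ndarray]
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {name: np.asarray(v).shape for name, v in self.channels.items()}
        ref = next(iter(shapes.values()))
        for name, shape in shapes.items():
            if len(shape) != 3:
                raise ValueError(f"channel {name!r} must be 3D (z,y,x), got shape {shape}")
            if shape != ref:
                raise FormatError(f"channel {name!r} has shape {shape}, expected {ref}")
        self.channels = {name: np.asarray(v) for name, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class PolylineROI:
    """A polyline tracing the proximal tubule, first vertex at the glomerular end.

    Vertices are ``(x, y)`` pixel coordinates. A straight line is simply a
    2-vertex polyline.
    """

    vertices: np.ndarray  # (n, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 2:
            raise ValueError("a polyline ROI needs at least 2 vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0, axis=1)):
            raise ValueError("consecutive ROI vertices must not coincide")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def check_bounds(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        if np.any(x < 0) or np.any(y < 0) or np.any(x > w - 1) or np.any(y > h - 1):
            raise ValueError(f"ROI vertices outside frame bounds {frame_shape}")

    def reversed(self) -> "PolylineROI":
        return PolylineROI(self.vertices[::-1].copy())


@dataclass
class ResultRow:
    """One analysed dataset: the snGFR estimate plus its provenance numbers."""

    dataset_id: str
    sngfr_nl_min: float
    r_squared: float | None
    pt_length_um: float
    pt_volume_um3: float
    threshold: float | None
    n_frames_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.sngfr_nl_min):
            raise ValueError("sngfr_nl_min must be finite")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        if self.pt_length_um < 0 or self.pt_volume_um3 < 0:
            raise ValueError("lengths and volumes must be non-negative")


RESULT_COLUMNS = [
    "dataset_id",
    "sngfr_nl_min",
    "r_squared",
    "pt_length_um",
    "pt_volume_um3",
    "threshold",
    "n_frames_used",
]


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def read_frame_series(path: str | Path, meta: AcquisitionMeta) -> FrameSeries:
    """Read a multi-page grayscale TIFF as a time series (one page per frame)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    for i, p in enumerate(pages):
        if p.ndim != 2:
            raise FormatError(f"page {i} of {path.name} is not grayscale 2D (shape {p.shape})")
        if p.shape != pages[0].shape:
            raise FormatError(
                f"page {i} of {path.name} has shape {p.shape}, expected {pages[0].shape}"
            )
    if len(pages) < 2:
        raise FormatError("at least 2 frames required in a time series TIFF")
    return FrameSeries(np.stack(pages), meta)


def write_frame_series(series: FrameSeries | np.ndarray, path: str | Path) -> Path:
    """Write a (t, y, x) array as a multi-page TIFF, one page per frame."""
    frames = series.frames if isinstance(series, FrameSeries) else np.asarray(series)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, frames, photometric="minisblack")
    return path


def read_channel_volumes(
    paths: Mapping[str, str | Path] | str | Path,
    meta: AcquisitionMeta,
    names: Sequence[str] | None = None,
    axis_order: str = "czyx",
) -> ChannelVolumes:
    """Read z-stacks into a :class:`ChannelVolumes`.

    ``paths`` is either a mapping ``{channel name: single-channel TIFF}`` or one
    multi-channel TIFF whose axis order is declared by ``axis_order``
    (``"czyx"`` or ``"zcyx"``); ``names`` then labels the channel axis.
    """
    if isinstance(paths, (str, Path)):
        arr = tifffile.imread(paths)
        if arr.ndim != 4:
            raise FormatError(
                f"multi-channel stack must be 4D ({axis_order}), got shape {arr.shape}"
            )
        if axis_order == "czyx":
            pass
        elif axis_order == "zcyx":
            arr = np.moveaxis(arr, 1, 0)
        else:
            raise FormatError(f"unknown axis order {axis_order!r}")
        if names is None or len(names) != arr.shape[0]:
            raise FormatError(
                f"need {arr.shape[0]} channel names for the channel axis, got {names!r}"
            )
        return ChannelVolumes({n: arr[i] for i, n in enumerate(names)}, meta)

    channels: dict[str, np.ndarray] = {}
    for name, p in paths.items():
        vol = tifffile.imread(p)
        if vol.ndim != 3:
            raise FormatError(f"channel {name!r} stack must be 3D (z,y,x), got {vol.shape}")
        channels[name] = vol
    return ChannelVolumes(channels, meta)


def write_volume(volume: np.ndarray, path: str | Path) -> Path:
    """Write a (z, y, x) raster as a multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(volume), photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def read_polyline_roi(path: str | Path) -> PolylineROI:
    """Read a polyline ROI from the native JSON dialect or an ImageJ ``.roi`` file.

    The native format is ``{"vertices": [[x, y], ...]}``. ImageJ ``.roi``
    files are accepted for the line/polyline subtypes (read-only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".roi":
        return _read_imagej_roi(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed ROI file {path.name}: {exc}") from exc
    if not isinstance(payload, dict) or "vertices" not in payload:
        raise FormatError(f"{path.name}: expected an object with a 'vertices' key")
    return PolylineROI(np.asarray(payload["vertices"], dtype=float))


def write_polyline_roi(roi: PolylineROI, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"vertices": roi.vertices.tolist()}, indent=1))
    return path


# ImageJ .roi layout (big-endian): magic "Iout", version, type byte at offset 6,
# top/left/bottom/right int16 at 8..16, nCoordinates at 16, coordinate int16
# pairs (all x, then all y, relative to left/top) from offset 64.
_IJ_POLYLINE = 6
_IJ_LINE = 5
_IJ_FREELINE = 7


def _read_imagej_roi(path: Path) -> PolylineROI:
    data = path.read_bytes()
    if len(data) < 64 or data[:4] != b"Iout":
        raise FormatError(f"{path.name} is not an ImageJ ROI file")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    if roi_type == _IJ_LINE:
        x1, y1, x2, y2 = struct.unpack(">4f", data[18:34])
        return PolylineROI(np.array([[x1, y1], [x2, y2]]))
    if roi_type not in (_IJ_POLYLINE, _IJ_FREELINE):
        raise FormatError(
            f"{path.name}: ROI type {roi_type} is not a line or polyline"
        )
    (n,) = struct.unpack(">h", data[16:18])
    if n < 2:
        raise FormatError(f"{path.name}: polyline with fewer than 2 vertices")
    coords = struct.unpack(f">{2 * n}h", data[64 : 64 + 4 * n])
    xs = np.asarray(coords[:n], dtype=float) + left
    ys = np.asarray(coords[n:], dtype=float) + top
    return PolylineROI(np.column_stack([xs, ys]))


# ---------------------------------------------------------------------------
# Metadata sidecar and result tables
# ---------------------------------------------------------------------------

def read_meta(path: str | Path) -> AcquisitionMeta:
    """Read acquisition metadata from a YAML/JSON sidecar config.

    Required keys: ``pixel_size_um``, ``voxel_depth_um``, ``frame_rate_fps``.
    Missing metadata is an error — silently assumed units would corrupt snGFR
    by orders of magnitude.
    """
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise FormatError(f"{path}: metadata config must be a mapping")
    missing = [k for k in ("pixel_size_um", "voxel_depth_um", "frame_rate_fps") if k not in payload]
    if missing:
        raise FormatError(f"{path}: missing metadata keys {missing}")
    return AcquisitionMeta(
        pixel_size_um=float(payload["pixel_size_um"]),
        voxel_depth_um=float(payload["voxel_depth_um"]),
        frame_rate_fps=float(payload["frame_rate_fps"]),
    )


def write_results(rows: Sequence[ResultRow], path: str | Path) -> Path:
    """Write result rows to CSV with ≥6 significant digits per number."""
    if not rows:
        raise ValueError("at least one result row required")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id,
                "sngfr_nl_min": r.sngfr_nl_min,
                "r_squared": r.r_squared,
                "pt_length_um": r.pt_length_um,
                "pt_volume_um3": r.pt_volume_um3,
                "threshold": r.threshold,
                "n_frames_used": r.n_frames_used,
            }
            for r in rows
        ],
        columns=RESULT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_results(path: str | Path) -> list[ResultRow]:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: result table missing columns {missing}")
    rows = []
    for _, rec in df.iterrows():
        rows.append(
            ResultRow(
                dataset_id=str(rec["dataset_id"]),
                sngfr_nl_min=float(rec["sngfr_nl_min"]),
                r_squared=None if pd.isna(rec["r_squared"]) else float(rec["r_squared"]),
                pt_length_um=float(rec["pt_length_um"]),
                pt_volume_um3=float(rec["pt_volume_um3"]),
                threshold=None if pd.isna(rec["threshold"]) else float(rec["threshold"]),
                n_frames_used=int(rec["n_frames_used"]),
            )
        )
    return rows
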