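"""Synthetic phantom: a tubule filling with dye at a known volumetric flow.

The phantom renders everything the real acquisition provides — a 2D+t dye
time series at the tubule mid-plane, a co-registered multi-channel z-stack
(dye + vessel + nuclei), and the tracing ROI — from a geometric tube model
with a known ground-truth flow ``Q``. The dye front is modelled exactly as
the physical picture behind the estimator: an arclength cutoff ``s(t)``
solving ``V(s(t)) = Q·t`` that advances along the tube, rendered with a ~1 px
soft edge. There is no fluid-dynamics simulation, no reabsorption and no
photobleaching; the dye is freely filtered and non-resorbable by assumption.

Every random element (noise, nucleus placement) derives from the spec's seed,
so identical specs render identical data.

Geometry scaling: the phantom keeps the real acquisition's pixel size and
voxel depth but renders a small field of view; the default frame rate is
derived from a transit-fit rule (the front reaches the tube end at the last
frame) so that the dye transit is temporally resolved at the chosen field
size. The snGFR estimate is invariant to this choice because the µm³/frame →
nl/min conversion is exactly linear in the frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

from .io import AcquisitionMeta, ChannelVolumes, FrameSeries, PolylineROI

__all__ = ["PhantomSpec", "PhantomTruth", "default_spec", "render_phantom",
           "closed_form_cumvol", "front_position", "transit_frame_rate"]

DYE, VESSEL, NUCLEI = "dye", "vessel", "nuclei"


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic acquisition.

    ``radius_um`` may be a single value (constant radius) or ``(r0, r1)``
    for a linear taper from the glomerular to the distal end.
    ``centerline`` is ``"straight"``, ``"arc"`` (circular bow of sagitta
    ``bend_amplitude_px``) or ``"sine"`` (one period, same amplitude).
    """

    stack_shape: tuple[int, int, int] = (20, 64, 64)  # (z, y, x)
    n_frames: int = 30
    centerline: str = "straight"
    radius_um: float | tuple[float, float] = 7.5
    bend_amplitude_px: float = 6.0
    margin_px: int = 4
    flow_nl_min: float = 1.7
    intensity_max: float = 200.0
    noise_sigma: float = 0.0  # fraction of intensity_max
    bleed_fractions: Mapping[str, float] = field(
        default_factory=lambda: {VESSEL: 0.2, NUCLEI: 0.1}
    )
    edge_softness_px: float = 1.0
    roi_inset_px: float = 3.0  # the traced ROI starts/ends inside the tube
    decoy: bool = False
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flow_nl_min <= 0 or self.intensity_max <= 0:
            raise ValueError("flow and intensity must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        r0, r1 = self.radii
        if r0 <= 0 or r1 <= 0:
            raise ValueError("radius must be positive")
        nz, ny, nx = self.stack_shape
        rmax_vox_z = max(r0, r1) / self.meta.voxel_depth_um
        rmax_vox_y = max(r0, r1) / self.meta.pixel_size_um
        cz = nz / 2.0
        if cz - rmax_vox_z < 2 or (nz - cz) - rmax_vox_z < 2:
            raise ValueError("tube does not fit in z with a 2-voxel margin")
        if ny / 2.0 - rmax_vox_y - self.bend_px < 2:
            raise ValueError("tube does not fit in y with a 2-voxel margin")
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames for a usable transit")

    @property
    def radii(self) -> tuple[float, float]:
        r = self.radius_um
        return (float(r), float(r)) if np.isscalar(r) else (float(r[0]), float(r[1]))

    @property
    def bend_px(self) -> float:
        return 0.0 if self.centerline == "straight" else float(self.bend_amplitude_px)

    # -- geometry -----------------------------------------------------------

    def centerline_px(self, step_px: float = 0.25) -> np.ndarray:
        """Densely sampled centerline in (x, y) pixel coordinates."""
        _, ny, nx = self.stack_shape
        x0, x1 = float(self.margin_px), float(nx - 1 - self.margin_px)
        cy = ny / 2.0
        x = np.arange(x0, x1 + step_px / 2, step_px)
        if self.centerline == "straight":
            y = np.full_like(x, cy)
        elif self.centerline == "arc":
            # circular bow through the endpoints with the given sagitta
            h = self.bend_px
            half = (x1 - x0) / 2.0
            radius = (half**2 + h**2) / (2.0 * h)
            yc = cy + radius - h
            y = yc - np.sqrt(np.maximum(radius**2 - (x - (x0 + half)) ** 2, 0.0))
        elif self.centerline == "sine":
            y = cy + self.bend_px * np.sin(2 * np.pi * (x - x0) / (x1 - x0))
        else:
            raise ValueError(f"unknown centerline type {self.centerline!r}")
        return np.column_stack([x, y])

    @property
    def length_um(self) -> float:
        pts = self.centerline_px()
        d = np.diff(pts, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum() * self.meta.pixel_size_um)

    def radius_at(self, s_um: np.ndarray | float) -> np.ndarray | float:
        r0, r1 = self.radii
        return r0 + (r1 - r0) * np.asarray(s_um) / self.length_um

    @property
    def flow_um3_per_frame(self) -> float:
        return self.flow_nl_min * 1.0e6 / 60.0 / self.meta.frame_rate_fps

    def roi(self, vertex_spacing_px: float = 4.0) -> PolylineROI:
        """The tracing ROI: the sampled centerline, inset from the tube ends
        (2 vertices if straight) — as a user traces a segment of a tubule
        that continues beyond the measured stretch."""
        pts = self.centerline_px()
        d = np.hypot(*np.diff(pts, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(d)])
        keep = (cum >= self.roi_inset_px) & (cum <= cum[-1] - self.roi_inset_px)
        pts = pts[keep]
        if self.centerline == "straight":
            return PolylineROI(pts[[0, -1]])
        step = max(1, int(round(vertex_spacing_px / 0.25)))
        idx = np.arange(0, len(pts), step)
        if idx[-1] != len(pts) - 1:
            idx = np.append(idx, len(pts) - 1)
        return PolylineROI(pts[idx])


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rendered phantom.

    Arclengths in ``cumvol_fn`` and ``front_arclength_fn`` are measured from
    the rendered tube's upstream end; the traced ROI starts ``roi_offset_um``
    further downstream and spans ``length_um``.
    """

    tube_mask: np.ndarray  # (z, y, x) bool, voxel centers inside the tube
    cumvol_fn: Callable[[float], float]  # V(s), µm³, full tube
    front_arclength_fn: Callable[[float], float]  # s(t), t in frames
    q_nl_min: float
    length_um: float  # ROI arclength
    tube_length_um: float
    roi_offset_um: float
    diameters_um: np.ndarray  # true diameters at five stations along the ROI


def transit_frame_rate(
    flow_nl_min: float, total_volume_um3: float, n_frames: int
) -> float:
    """Frame rate at which the front exits the tube one frame before the series ends."""
    q_um3_s = flow_nl_min * 1.0e6 / 60.0
    return q_um3_s * (n_frames - 2) / total_volume_um3


def default_spec(
    flow_nl_min: float = 1.7,
    noise_sigma: float = 0.0,
    seed: int = 0,
    stack_shape: tuple[int, int, int] = (20, 64, 64),
    n_frames: int = 30,
    **kwargs,
) -> PhantomSpec:
    """A study-condition phantom: straight tube, 15 µm luminal diameter,
    the real acquisition's pixel size and voxel depth, and a frame rate set
    by the transit-fit rule for the given flow and geometry."""
    base = PhantomSpec(
        stack_shape=stack_shape,
        n_frames=n_frames,
        flow_nl_min=flow_nl_min,
        noise_sigma=noise_sigma,
        seed=seed,
        **kwargs,
    )
    total = closed_form_cumvol(base, base.length_um)
    fps = transit_frame_rate(flow_nl_min, total, n_frames)
    meta = AcquisitionMeta(
        pixel_size_um=base.meta.pixel_size_um,
        voxel_depth_um=base.meta.voxel_depth_um,
        frame_rate_fps=fps,
    )
    return replace(base, meta=meta)


def closed_form_cumvol(spec: PhantomSpec, s_um: float) -> float:
    """Analytic cumulative tube volume V(s) = π ∫₀ˢ r(u)² du.

    For a linear taper r(u) = r0 + k·u this is
    π (r0² s + r0 k s² + k² s³ / 3).
    """
    L = spec.length_um
    if not (0.0 <= s_um <= L + 1e-9):
        raise ValueError(f"arclength {s_um} outside [0, {L}]")
    r0, r1 = spec.radii
    k = (r1 - r0) / L
    return float(np.pi * (r0**2 * s_um + r0 * k * s_um**2 + k**2 * s_um**3 / 3.0))


def front_position(spec: PhantomSpec, t_frames: float) -> float:
    """Front arclength s(t) solving V(s) = Q·t, clipped to [0, L]."""
    if t_frames < 0:
        raise ValueError("time must be non-negative")
    L = spec.length_um
    target = spec.flow_um3_per_frame * t_frames
    total = closed_form_cumvol(spec, L)
    if target <= 0:
        return 0.0
    if target >= total:
        return L
    r0, r1 = spec.radii
    if r0 == r1:
        return float(target / (np.pi * r0**2))
    return float(brentq(lambda s: closed_form_cumvol(spec, s) - target, 0.0, L, xtol=1e-10))


def _front_position_unclipped(spec: PhantomSpec, t_frames: float) -> float:
    """As :func:`front_position` but continuing past the tube end, so the
    distal end of the rendered tube fills completely once the front exits."""
    L = spec.length_um
    target = spec.flow_um3_per_frame * t_frames
    total = closed_form_cumvol(spec, L)
    if target < total:
        return front_position(spec, t_frames)
    _, r1 = spec.radii
    return L + (target - total) / (np.pi * r1**2)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _project_to_dense_centerline(
    pts_xy_px: np.ndarray, center_px: np.ndarray, pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """(arclength µm, planar distance µm) of points w.r.t. the dense centerline."""
    verts = center_px
    seg = np.diff(verts, axis=0)
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    seg_len_um = np.sqrt(seg_len2) * pixel_size_um
    cum = np.concatenate([[0.0], np.cumsum(seg_len_um)])[:-1]
    rel = pts_xy_px[:, None, :] - verts[None, :-1, :]
    t = np.clip(np.einsum("nsj,sj->ns", rel, seg) / seg_len2[None, :], 0.0, 1.0)
    foot = verts[None, :-1, :] + t[..., None] * seg[None, :, :]
    d2 = ((pts_xy_px[:, None, :] - foot) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    n = np.arange(len(pts_xy_px))
    s_um = cum[best] + t[n, best] * seg_len_um[best]
    return s_um, np.sqrt(d2[n, best]) * pixel_size_um


def _coverage(signed: np.ndarray, edge_um: float) -> np.ndarray:
    """Soft inside/outside indicator: 1 deep inside, 0 outside, linear ramp."""
    if edge_um <= 0:
        return (signed >= 0).astype(float)
    return np.clip(0.5 + signed / edge_um, 0.0, 1.0)


def render_phantom(
    spec: PhantomSpec,
) -> tuple[FrameSeries, ChannelVolumes, PolylineROI, PhantomTruth]:
    """Render the full synthetic acquisition plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.stack_shape
    px, dz = spec.meta.pixel_size_um, spec.meta.voxel_depth_um
    M = spec.intensity_max
    edge_um = spec.edge_softness_px * px
    cz_um = nz / 2.0 * dz
    center = spec.centerline_px()

    # planar geometry shared by the z-stack and the time series
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    plane_pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    s_um, d_xy = _project_to_dense_centerline(plane_pts, center, px)
    s_um = s_um.reshape(ny, nx)
    d_xy = d_xy.reshape(ny, nx)
    # truncate the tube flat at s = 0 and s = L: pixels whose nearest foot
    # point clamps to a centerline endpoint are outside the tube (no end caps)
    first, last = center[0], center[-1]
    fdir = center[1] - center[0]
    ldir = center[-1] - center[-2]
    t0 = (plane_pts - first) @ fdir
    t1 = (plane_pts - last) @ ldir
    overhang = ((t0 < 0) | (t1 > 0)).reshape(ny, nx)
    d_xy = np.where(overhang, np.inf, d_xy)
    r_here = np.asarray(spec.radius_at(s_um))

    # ---- z-stack channels -------------------------------------------------
    z_um = (np.arange(nz) + 0.5) * dz  # voxel centers
    d3 = np.sqrt(d_xy[None, :, :] ** 2 + (z_um[:, None, None] - cz_um) ** 2)
    dye_cov = _coverage(r_here[None, :, :] - d3, edge_um)
    dye_clean = M * dye_cov
    tube_mask = d3 <= r_here[None, :, :]

    vessel_clean = _render_vessel(spec, d_xy_shape=(nz, ny, nx))
    nuclei_clean = _render_nuclei(spec, rng, center)

    if spec.decoy:
        dye_clean = dye_clean + _render_decoy(spec)
        # the decoy is a separate dye-filled structure, not part of the tubule truth

    bleed = dict(spec.bleed_fractions)
    dye_obs = dye_clean + bleed.get(VESSEL, 0.0) * vessel_clean + bleed.get(NUCLEI, 0.0) * nuclei_clean

    sigma = spec.noise_sigma * M
    channels = {}
    for name, clean in ((DYE, dye_obs), (VESSEL, vessel_clean), (NUCLEI, nuclei_clean)):
        noisy = clean if sigma == 0 else clean + rng.normal(0.0, sigma, clean.shape)
        channels[name] = np.clip(noisy, 0.0, None).astype(np.float32)
    volumes = ChannelVolumes(channels, spec.meta)

    # ---- time series at the tubule mid-plane ------------------------------
    mid_radial = _coverage(r_here - d_xy, edge_um)  # radial coverage at z = cz
    frames = np.empty((spec.n_frames, ny, nx), dtype=np.float32)
    for k in range(spec.n_frames):
        s_front = _front_position_unclipped(spec, float(k))
        # the front tip ends exactly at s(t): ramp over one edge width behind
        # it, so the pre-injection frame (s = 0) is genuinely blank
        axial = np.clip((s_front - s_um) / edge_um, 0.0, 1.0) if edge_um > 0 \
            else (s_um <= s_front).astype(float)
        frame = M * mid_radial * axial
        if sigma > 0:
            frame = frame + rng.normal(0.0, sigma, frame.shape)
        frames[k] = np.clip(frame, 0.0, None)
    series = FrameSeries(frames, spec.meta)

    # ---- truth ------------------------------------------------------------
    roi = spec.roi()
    offset_um = spec.roi_inset_px * px
    d = np.diff(roi.vertices, axis=0)
    roi_len_um = float(np.hypot(d[:, 0], d[:, 1]).sum() * px)
    stations = offset_um + np.linspace(0.1, 0.9, 5) * roi_len_um
    truth = PhantomTruth(
        tube_mask=tube_mask,
        cumvol_fn=lambda s: closed_form_cumvol(spec, s),
        front_arclength_fn=lambda t: front_position(spec, t),
        q_nl_min=spec.flow_nl_min,
        length_um=roi_len_um,
        tube_length_um=spec.length_um,
        roi_offset_um=offset_um,
        diameters_um=2.0 * np.asarray(spec.radius_at(stations)),
    )
    return series, volumes, roi, truth


def _render_vessel(spec: PhantomSpec, d_xy_shape: tuple[int, int, int]) -> np.ndarray:
    """A straight peritubular capillary parallel to the tubule, clear of it."""
    nz, ny, nx = d_xy_shape
    px, dz = spec.meta.pixel_size_um, spec.meta.voxel_depth_um
    vy_um = (ny * 0.15) * px
    vz_um = nz / 2.0 * dz
    r_v = 2.5
    y_um = (np.arange(ny) + 0.0) * px
    z_um = (np.arange(nz) + 0.5) * dz
    d = np.sqrt(
        (y_um[None, :, None] - vy_um) ** 2 + (z_um[:, None, None] - vz_um) ** 2
    )
    d = np.broadcast_to(d, (nz, ny, nx))
    return (0.8 * spec.intensity_max) * _coverage(r_v - d, spec.edge_softness_px * px)


def _render_nuclei(
    spec: PhantomSpec, rng: np.random.Generator, center_px: np.ndarray
) -> np.ndarray:
    """A handful of round nuclei scattered away from the tubule."""
    nz, ny, nx = spec.stack_shape
    px, dz = spec.meta.pixel_size_um, spec.meta.voxel_depth_um
    out = np.zeros((nz, ny, nx), dtype=float)
    r_n = 2.5
    rmax = max(spec.radii)
    n_placed = 0
    for _ in range(200):
        if n_placed >= 8:
            break
        cx, cy = rng.uniform(2, nx - 3), rng.uniform(2, ny - 3)
        czv = rng.uniform(2, nz - 3)
        s, d = _project_to_dense_centerline(np.array([[cx, cy]]), center_px, px)
        if d[0] < rmax + r_n + 2.0:  # keep clear of the tubule
            continue
        y_um = np.arange(ny) * px
        x_um = np.arange(nx) * px
        z_um = (np.arange(nz) + 0.5) * dz
        dist = np.sqrt(
            (x_um[None, None, :] - cx * px) ** 2
            + (y_um[None, :, None] - cy * px) ** 2
            + (z_um[:, None, None] - czv * dz) ** 2
        )
        out = np.maximum(out, 0.6 * spec.intensity_max * _coverage(r_n - dist, px))
        n_placed += 1
    return out


def _render_decoy(spec: PhantomSpec) -> np.ndarray:
    """A bright dye-filled blob away from the tubule, to exercise label selection."""
    nz, ny, nx = spec.stack_shape
    px, dz = spec.meta.pixel_size_um, spec.meta.voxel_depth_um
    cx, cy, czv = nx * 0.2 * px, ny * 0.82 * px, nz / 2.0 * dz
    r_d = 4.0
    x_um = np.arange(nx) * px
    y_um = np.arange(ny) * px
    z_um = (np.arange(nz) + 0.5) * dz
    dist = np.sqrt(
        (x_um[None, None, :] - cx) ** 2
        + (y_um[None, :, None] - cy) ** 2
        + (z_um[:, None, None] - czv) ** 2
    )
    return spec.intensity_max * _coverage(r_d - dist, px)
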