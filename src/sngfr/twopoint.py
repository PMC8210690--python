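"""The legacy two-point snGFR estimate: cylinder volume over transit time.

The previously published approach measures intensity-over-time at just two
points along the proximal tubule, takes the transit time of the dye front
between them, and divides the tubule volume between the points — modelled as
a cylinder whose diameter is the mean of five manual diameter measurements —
by that transit time. It is implemented here as the comparison baseline for
the continuous estimator.

Arrival at a point is defined by the frame of maximum forward difference of
the (optionally smoothed) intensity curve — the same turning-point estimator
the continuous workflow uses for its threshold — so that the comparison
isolates the structural difference between the methods (two points + cylinder
vs continuous tracking + 3D volume) rather than differing arrival detectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ResultRow

__all__ = ["TwoPointInput", "cylinder_volume", "transit_time", "twopoint_sngfr", "twopoint_result"]


@dataclass
class TwoPointInput:
    """Curves at the upstream/downstream points plus the manual measurements."""

    curve_a: np.ndarray  # upstream (glomerular) point, intensity per frame
    curve_b: np.ndarray  # downstream point
    diameters_um: np.ndarray  # manual diameter measurements (default workflow: five)
    distance_um: float  # arclength between the two points
    frame_rate_fps: float

    def __post_init__(self) -> None:
        self.curve_a = np.asarray(self.curve_a, dtype=float)
        self.curve_b = np.asarray(self.curve_b, dtype=float)
        self.diameters_um = np.atleast_1d(np.asarray(self.diameters_um, dtype=float))
        if self.curve_a.shape != self.curve_b.shape or self.curve_a.ndim != 1:
            raise ValueError("curves must be 1D and of equal length")
        if len(self.curve_a) < 3:
            raise ValueError("curves need at least 3 frames")
        if len(self.diameters_um) < 1 or np.any(self.diameters_um <= 0):
            raise ValueError("at least one positive diameter required")
        if self.distance_um <= 0:
            raise ValueError("distance between points must be positive")
        if self.frame_rate_fps <= 0:
            raise ValueError("frame rate must be positive")


def cylinder_volume(diameters_um: Sequence[float], length_um: float) -> float:
    """Cylinder volume from the mean of the manual diameters: π (d̄/2)² L."""
    d = np.atleast_1d(np.asarray(diameters_um, dtype=float))
    if np.any(d <= 0) or length_um <= 0:
        raise ValueError("diameters and length must be positive")
    mean_d = float(d.mean())
    return float(np.pi * (mean_d / 2.0) ** 2 * length_um)


def _arrival_frame(curve: np.ndarray, smooth_window: int = 1) -> int:
    curve = np.asarray(curve, dtype=float)
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        kernel = np.ones(smooth_window)
        curve = np.convolve(curve, kernel, mode="same") / np.convolve(
            np.ones(len(curve)), kernel, mode="same"
        )
    diffs = np.diff(curve)
    m = diffs.max()
    if m <= 0:
        raise ValueError("curve shows no rise; cannot detect dye arrival")
    # middle of the maximal-slope run: deterministic for smoothed sharp steps
    cand = np.nonzero(diffs >= m - 1e-9 * abs(m))[0]
    return int(cand[len(cand) // 2])


def transit_time(
    curve_a: np.ndarray,
    curve_b: np.ndarray,
    frame_rate_fps: float,
    smooth_window: int = 1,
) -> float:
    """Seconds between dye arrival at the upstream and downstream points.

    Arrival is the frame of maximum forward difference. A non-positive
    transit (downstream rising at or before upstream) is an error.
    """
    ka = _arrival_frame(curve_a, smooth_window)
    kb = _arrival_frame(curve_b, smooth_window)
    dt = (kb - ka) / frame_rate_fps
    if dt <= 0:
        raise ValueError(
            f"downstream point rises before upstream point (Δt = {dt:.3g} s)"
        )
    return float(dt)


def twopoint_sngfr(inp: TwoPointInput, smooth_window: int = 1) -> float:
    """snGFR (nl/min) = cylinder volume / transit time, converted from µm³/s."""
    vol = cylinder_volume(inp.diameters_um, inp.distance_um)
    dt = transit_time(inp.curve_a, inp.curve_b, inp.frame_rate_fps, smooth_window)
    return vol / dt * 60.0 / 1.0e6


def twopoint_result(dataset_id: str, inp: TwoPointInput, smooth_window: int = 1) -> ResultRow:
    """Shared result-row schema; R² is not defined for the two-point method."""
    return ResultRow(
        dataset_id=dataset_id,
        sngfr_nl_min=twopoint_sngfr(inp, smooth_window),
        r_squared=None,
        pt_length_um=inp.distance_um,
        pt_volume_um3=cylinder_volume(inp.diameters_um, inp.distance_um),
        threshold=None,
        n_frames_used=len(inp.curve_a),
    )
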