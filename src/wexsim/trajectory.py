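"""Sequence timing arithmetic and 3D radial spiral-phyllotaxis trajectories.

A whole-heart 3D radial acquisition collects one spiral *segment* of readout
lines per heartbeat inside a fixed diastolic window; successive segments are
rotated about the superior-inferior (+z) axis by the golden angle
(~137.51 deg).  Within a segment the spoke polar angle grows with the square
root of the sample index (sunflower-seed spacing over the hemisphere) while
the azimuth advances by the same divergence angle, and — for respiratory
self-navigation — the first spoke of every segment can repeat the +z
orientation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pulses import ParameterError

__all__ = [
    "GOLDEN_ANGLE",
    "AcquisitionPlan",
    "lines_per_window",
    "phyllotaxis",
    "scan_time",
    "directions_to_dataframe",
]

#: Golden angle in degrees.
GOLDEN_ANGLE = 137.51


@dataclass(frozen=True)
class AcquisitionPlan:
    """Segmented acquisition bookkeeping (times in ms)."""

    tr: float
    te: float
    window: float
    n_segments: int
    lines_per_segment: int

    def __post_init__(self) -> None:
        if self.lines_per_segment * self.tr > self.window + 1e-9:
            raise ParameterError(
                f"{self.lines_per_segment} lines x TR {self.tr} ms exceed the "
                f"{self.window} ms window"
            )

    @property
    def total_lines(self) -> int:
        return self.n_segments * self.lines_per_segment


def lines_per_window(window: float, tr: float) -> int:
    """Readout lines fitting in an acquisition window: floor(window / tr).

    Units must match (both ms or both s).  With the 100 ms diastolic window,
    TR 4.30 ms gives 23 lines and TR 5.53 ms gives 18.
    """
    if window <= 0 or tr <= 0:
        raise ParameterError("window and tr must be > 0")
    return int(math.floor(window / tr))


def scan_time(n_segments: int, heartbeats_per_min: float) -> float:
    """Total scan time in seconds at one segment per heartbeat."""
    if n_segments < 0 or heartbeats_per_min <= 0:
        raise ParameterError("need n_segments >= 0 and heart rate > 0")
    return n_segments * 60.0 / heartbeats_per_min


def phyllotaxis(
    n_segments: int,
    lines_per_segment: int,
    golden_angle: float = GOLDEN_ANGLE,
    si_leading: bool = True,
) -> np.ndarray:
    """Unit k-space spoke directions, shape (n_segments, lines_per_segment, 3).

    Within segment m, non-SI line k points at polar angle
    ``(pi/2) * sqrt(k / k_max)`` (square-root spacing from pole to equator)
    and azimuth ``k * golden_angle + m * golden_angle``; each spoke spans the
    full k-space diameter (+/- k_max along the direction).  With
    ``si_leading`` (default) line 0 of every segment is the +z spoke used for
    respiratory self-navigation.
    """
    if n_segments < 1 or lines_per_segment < 1:
        raise ParameterError("counts must be >= 1")
    ga = np.deg2rad(golden_angle)
    out = np.empty((n_segments, lines_per_segment, 3))
    n = lines_per_segment
    for m in range(n_segments):
        if si_leading:
            ks = np.arange(n, dtype=float)  # k=0 -> pole (the SI spoke itself)
            denom = max(n - 1, 1)
            theta = 0.5 * np.pi * np.sqrt(ks / denom)
        else:
            ks = np.arange(1, n + 1, dtype=float)
            theta = 0.5 * np.pi * np.sqrt(ks / n)
        phi = ks * ga + m * ga
        out[m, :, 0] = np.sin(theta) * np.cos(phi)
        out[m, :, 1] = np.sin(theta) * np.sin(phi)
        out[m, :, 2] = np.cos(theta)
    return out


def directions_to_dataframe(directions: np.ndarray) -> pd.DataFrame:
    """Long-format (segment, line, kx, ky, kz) table of a direction array."""
    ns, nl, _ = directions.shape
    seg, line = np.meshgrid(np.arange(ns), np.arange(nl), indexing="ij")
    return pd.DataFrame(
        {
            "segment": seg.ravel(),
            "line": line.ravel(),
            "kx": directions[..., 0].ravel(),
            "ky": directions[..., 1].ravel(),
            "kz": directions[..., 2].ravel(),
        }
    )


def trajectory_header(
    n_segments: int, lines_per_segment: int, golden_angle: float = GOLDEN_ANGLE,
    si_leading: bool = True
) -> str:
    """JSON header describing a generated trajectory."""
    return json.dumps(
        {
            "n_segments": n_segments,
            "lines_per_segment": lines_per_segment,
            "total_lines": n_segments * lines_per_segment,
            "golden_angle_deg": golden_angle,
            "si_leading": si_leading,
            "convention": "+z is superior-inferior; spokes span +/- k_max",
        },
        indent=2,
    )
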