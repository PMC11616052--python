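"""Rotating-frame Bloch propagation for piecewise-constant RF pulses.

Everything here works in the water rotating frame.  A tissue is described by
its chemical-shift frequency ``freq`` relative to water (fat at 3T: -440 Hz),
T1 and T2.  Positive frequency precesses counter-clockwise about +z.

Within one RF segment the effective field is constant in the frame rotating
at the segment's transmit offset, so the propagator is a single closed-form
rotation: about the axis ``(amplitude*cos(phi), amplitude*sin(phi),
tissue_freq - freq_offset)`` (all in Hz) by ``2*pi*|axis|*duration``,
followed by the z-rotation ``360*freq_offset*duration`` that carries the
result back to the water frame.  Relaxation during RF is neglected (segments
are <= 1.1 ms, far below T2); relaxation enters only between excitations of
the spoiled-GRE loop.

The spoiled gradient-echo steady state is simulated literally: excite,
record |Mxy|, null the transverse magnetization (perfect spoiling), relax
longitudinally over TR, repeat.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pulses import ParameterError, RFPulse, RFSegment

__all__ = [
    "Tissue",
    "SequenceParams",
    "ResponseMap",
    "EQUILIBRIUM",
    "DEFAULT_FREQ_GRID",
    "DEFAULT_PHASE_GRID",
    "DEFAULT_ANGLE_GRID",
    "FAT_FREQ_3T",
    "segment_rotation",
    "propagate_segment",
    "pulse_rotation",
    "apply_pulse",
    "water_rotation_angle",
    "required_set_angle",
    "frequency_profile",
    "phase_sweep",
    "gre_steady_state",
]

#: Equilibrium magnetization (Mx, My, Mz).
EQUILIBRIUM = np.array([0.0, 0.0, 1.0])

#: Fat chemical shift relative to water at 3T, Hz.
FAT_FREQ_3T = -440.0

#: Off-resonance grid -800..800 Hz in 5 Hz steps (321 points).
DEFAULT_FREQ_GRID = np.arange(-800.0, 801.0, 5.0)

#: Phase-modulation grid 0..360 deg in 5 deg steps (73 points).
DEFAULT_PHASE_GRID = np.arange(0.0, 361.0, 5.0)

#: Excitation-angle grid 2..30 deg in 2 deg steps (15 points).
DEFAULT_ANGLE_GRID = np.arange(2.0, 31.0, 2.0)


@dataclass(frozen=True)
class Tissue:
    """Tissue relaxation and chemical-shift parameters (SI units)."""

    t1: float
    t2: float
    freq: float = 0.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t1 >= self.t2 > 0):
            raise ParameterError(f"require t1 >= t2 > 0, got t1={self.t1}, t2={self.t2}")


@dataclass(frozen=True)
class SequenceParams:
    """Spoiled-GRE sequence parameters."""

    tr: float
    te: float = 0.0
    n_excitations: int = 500
    spoiling: str = "perfect"

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ParameterError(f"TR must be > 0, got {self.tr}")
        if not (0 <= self.te < self.tr):
            raise ParameterError(f"require 0 <= TE < TR, got TE={self.te}, TR={self.tr}")
        if self.n_excitations < 1:
            raise ParameterError("n_excitations must be >= 1")
        if self.spoiling != "perfect":
            raise ParameterError("only perfect spoiling is supported")


@dataclass
class ResponseMap:
    """|Mxy| (and Mz) over a frequency grid, optionally with a second axis.

    ``mxy``/``mz`` have shape ``(len(axis2), len(freq))`` when ``axis2`` is
    present, else ``(len(freq),)``.
    """

    freq: np.ndarray
    mxy: np.ndarray
    mz: np.ndarray | None = None
    axis2_name: str | None = None
    axis2: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, float)
        self.mxy = np.asarray(self.mxy, float)
        if self.freq.ndim != 1 or not np.all(np.diff(self.freq) > 0):
            raise ParameterError("frequency grid must be 1-D and strictly increasing")
        if self.mxy.shape[-1] != self.freq.size:
            raise ParameterError("mxy last axis must match the frequency grid")

    @property
    def is_2d(self) -> bool:
        return self.axis2 is not None

    def row(self, value: float) -> "ResponseMap":
        """Extract the 1-D profile at the axis-2 grid point nearest ``value``."""
        if not self.is_2d:
            raise ParameterError("row() requires a 2-D map")
        i = int(np.argmin(np.abs(np.asarray(self.axis2) - value)))
        return ResponseMap(
            self.freq,
            self.mxy[i],
            None if self.mz is None else self.mz[i],
            meta={**self.meta, self.axis2_name or "axis2": float(self.axis2[i])},
        )

    def to_dataframe(self) -> pd.DataFrame:
        if self.is_2d:
            a2, f = np.meshgrid(self.axis2, self.freq, indexing="ij")
            d = {self.axis2_name or "axis2": a2.ravel(), "freq_hz": f.ravel(),
                 "mxy": self.mxy.ravel()}
            if self.mz is not None:
                d["mz"] = self.mz.ravel()
        else:
            d = {"freq_hz": self.freq, "mxy": self.mxy}
            if self.mz is not None:
                d["mz"] = self.mz
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def meta_json(self) -> str:
        meta = dict(self.meta)
        meta["freq_grid_hz"] = [float(self.freq[0]), float(self.freq[-1]),
                                float(self.freq[1] - self.freq[0])]
        if self.is_2d:
            meta["axis2_name"] = self.axis2_name
            meta["axis2"] = [float(v) for v in self.axis2]
        return json.dumps(meta, indent=2)

    def save_heatmap(self, path, **imshow_kw) -> None:
        """Render a 2-D map as a heatmap image (requires matplotlib)."""
        if not self.is_2d:
            raise ParameterError("heatmap export requires a 2-D map")
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        extent = [self.freq[0], self.freq[-1], self.axis2[0], self.axis2[-1]]
        im = ax.imshow(self.mxy, origin="lower", aspect="auto", extent=extent,
                       **imshow_kw)
        ax.set_xlabel("off-resonance (Hz)")
        ax.set_ylabel(self.axis2_name or "axis2")
        fig.colorbar(im, ax=ax, label="|Mxy|")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


# ---------------------------------------------------------------------------
# rotation kernels
# ---------------------------------------------------------------------------

def _rodrigues(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotation matrices for unit axes (..., 3) and angles (...) in radians."""
    x, y, z = axis[..., 0], axis[..., 1], axis[..., 2]
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    R = np.empty(axis.shape[:-1] + (3, 3))
    R[..., 0, 0] = c + x * x * C
    R[..., 0, 1] = x * y * C - z * s
    R[..., 0, 2] = x * z * C + y * s
    R[..., 1, 0] = y * x * C + z * s
    R[..., 1, 1] = c + y * y * C
    R[..., 1, 2] = y * z * C - x * s
    R[..., 2, 0] = z * x * C - y * s
    R[..., 2, 1] = z * y * C + x * s
    R[..., 2, 2] = c + z * z * C
    return R


def _rot_z(angle: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    R = np.zeros(np.shape(angle) + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


def segment_rotation(
    seg: RFSegment, tissue_freq: float | np.ndarray, t0: float = 0.0
) -> np.ndarray:
    """Water-frame propagator of one segment, vectorized over ``tissue_freq``.

    ``t0`` is the segment's start time relative to the start of its pulse; it
    feeds the carrier phase accumulated by preceding segments
    (``phase + 360*freq_offset*t0``), so that carrier-referenced phases
    compose correctly when segments are chained.
    """
    f = np.atleast_1d(np.asarray(tissue_freq, float))
    dfz = f - seg.freq_offset
    phi = np.deg2rad(seg.phase + 360.0 * seg.freq_offset * t0)
    bx = np.full_like(f, seg.amplitude * np.cos(phi))
    by = np.full_like(f, seg.amplitude * np.sin(phi))
    omega = np.stack([bx, by, dfz], axis=-1)
    norm = np.linalg.norm(omega, axis=-1)
    angle = 2.0 * np.pi * norm * seg.duration
    safe = np.where(norm == 0.0, 1.0, norm)
    R = _rodrigues(omega / safe[..., None], angle)
    R[norm == 0.0] = np.eye(3)
    # back to the water frame: undo the transmit-frame rotation over duration
    Rz = _rot_z(np.full_like(f, 2.0 * np.pi * seg.freq_offset * seg.duration))
    out = Rz @ R
    return out[0] if np.isscalar(tissue_freq) or np.ndim(tissue_freq) == 0 else out


def propagate_segment(
    m: np.ndarray, seg: RFSegment, tissue_freq: float, t0: float = 0.0
) -> np.ndarray:
    """Propagate a magnetization 3-vector through one segment (no relaxation)."""
    return segment_rotation(seg, tissue_freq, t0) @ np.asarray(m, float)


def pulse_rotation(pulse: RFPulse, tissue_freq: float | np.ndarray) -> np.ndarray:
    """Composed water-frame propagator of a whole pulse over a frequency grid."""
    f = np.atleast_1d(np.asarray(tissue_freq, float))
    R = np.broadcast_to(np.eye(3), f.shape + (3, 3)).copy()
    t0 = 0.0
    for seg in pulse.segments:
        R = segment_rotation(seg, f, t0) @ R
        t0 += seg.duration
    return R[0] if np.isscalar(tissue_freq) or np.ndim(tissue_freq) == 0 else R


def apply_pulse(m: np.ndarray, pulse: RFPulse, tissue_freq: float) -> np.ndarray:
    """Apply a pulse to a magnetization vector at one tissue frequency."""
    return pulse_rotation(pulse, tissue_freq) @ np.asarray(m, float)


def water_rotation_angle(pulse: RFPulse) -> float:
    """Rotation of the water magnetization (deg): arccos(Mz) from equilibrium.

    This is the *nominal* excitation angle of Table-style pulse comparisons;
    for off-resonant pulses it is smaller than the set angle.
    """
    m = apply_pulse(EQUILIBRIUM, pulse, 0.0)
    return float(np.degrees(np.arccos(np.clip(m[2], -1.0, 1.0))))


def required_set_angle(
    pulse_factory: Callable[[float], RFPulse],
    nominal: float,
    resolution: float = 1.0,
    max_angle: float = 360.0,
) -> float:
    """Set angle whose water rotation equals ``nominal`` (deg), by bisection.

    ``pulse_factory`` maps a set angle to a pulse with fixed tau/f_rf/phase.
    The water rotation is assumed (and asserted) monotone in the set angle
    over the bracket.  The continuous solution is rounded to ``resolution``
    (ties toward the smaller angle).

    Raises
    ------
    ParameterError
        If ``nominal`` is outside (0, 90) or unreachable below ``max_angle``.
    """
    if not (0.0 < nominal < 90.0):
        raise ParameterError(f"nominal angle must be in (0, 90), got {nominal}")

    def rot(a: float) -> float:
        return water_rotation_angle(pulse_factory(a))

    # walk up from zero to find the first bracket containing the target,
    # asserting monotonicity of the sampled walk on the way
    step = 5.0
    lo, prev = 0.0, 0.0
    hi = None
    a = step
    while a <= max_angle + 1e-9:
        r = rot(a)
        if r < prev - 1e-9:
            raise ParameterError(
                "water rotation is not monotone over the search bracket"
            )
        if r >= nominal:
            hi = a
            break
        lo, prev = a, r
        a += step
    if hi is None:
        raise ParameterError(
            f"water rotation never reaches nominal {nominal} deg below "
            f"{max_angle} deg"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if rot(mid) < nominal:
            lo = mid
        else:
            hi = mid
    x = 0.5 * (lo + hi)
    n = np.floor(x / resolution + 0.5)
    if (x / resolution + 0.5) - np.floor(x / resolution + 0.5) == 0.0:
        n -= 1.0  # half-way ties toward the smaller angle
    return float(max(resolution, n * resolution))


def frequency_profile(
    pulse: RFPulse, freq_grid: Sequence[float] | np.ndarray = DEFAULT_FREQ_GRID
) -> ResponseMap:
    """|Mxy| and Mz after a single excitation from equilibrium, per frequency."""
    f = np.asarray(freq_grid, float)
    R = pulse_rotation(pulse, f)
    m = R @ EQUILIBRIUM
    return ResponseMap(
        f,
        np.hypot(m[..., 0], m[..., 1]),
        m[..., 2],
        meta={"pulse": pulse.to_dict(), "excitations": 1},
    )


def phase_sweep(
    pulse_factory: Callable[[float], RFPulse],
    phase_grid: Sequence[float] | np.ndarray = DEFAULT_PHASE_GRID,
    freq_grid: Sequence[float] | np.ndarray = DEFAULT_FREQ_GRID,
) -> ResponseMap:
    """Single-excitation |Mxy| over (phase modulation x off-resonance).

    ``pulse_factory`` maps a phase offset (deg) to a pulse; the default grids
    reproduce the 73 x 321 map used to select the LIBOR phase.
    """
    phases = np.asarray(phase_grid, float)
    f = np.asarray(freq_grid, float)
    mxy = np.empty((phases.size, f.size))
    mz = np.empty_like(mxy)
    for i, dphi in enumerate(phases):
        prof = frequency_profile(pulse_factory(float(dphi)), f)
        mxy[i] = prof.mxy
        mz[i] = prof.mz
    return ResponseMap(f, mxy, mz, axis2_name="phase_deg", axis2=phases)


def gre_steady_state(
    pulse: RFPulse,
    seq: SequenceParams,
    tissue: Tissue,
    freq_grid: Sequence[float] | np.ndarray = DEFAULT_FREQ_GRID,
    angle_grid: Sequence[float] | np.ndarray | None = DEFAULT_ANGLE_GRID,
) -> ResponseMap:
    """Spoiled-GRE |Mxy| after ``seq.n_excitations`` excitations.

    Per (set angle, frequency): apply the pulse, record |Mxy|, null the
    transverse magnetization (perfect spoiling) and recover Mz toward m0 over
    TR.  T1 recovery uses the full TR interval; the recorded signal is |Mxy|
    immediately after excitation (no TE decay).  With ``angle_grid=None`` the
    pulse's own set angle is used and a 1-D map is returned.
    """
    f = np.asarray(freq_grid, float)
    single = angle_grid is None
    angles = np.array([pulse.set_angle]) if single else np.asarray(angle_grid, float)
    e1 = np.exp(-seq.tr / tissue.t1)
    mxy = np.empty((angles.size, f.size))
    mz_out = np.empty_like(mxy)
    for i, a in enumerate(angles):
        R = pulse_rotation(pulse.scaled(float(a)), f)
        c = np.hypot(R[..., 0, 2], R[..., 1, 2])  # |Mxy| produced from pure Mz
        rzz = R[..., 2, 2]
        mz = np.full(f.shape, tissue.m0)  # longitudinal state before each pulse
        for _ in range(seq.n_excitations):
            sig = c * mz
            mz_after = rzz * mz
            mz = tissue.m0 + (mz_after - tissue.m0) * e1
        mxy[i] = sig
        mz_out[i] = mz_after
    meta = {
        "pulse": pulse.to_dict(),
        "tr_s": seq.tr,
        "t1_s": tissue.t1,
        "t2_s": tissue.t2,
        "n_excitations": seq.n_excitations,
    }
    if single:
        return ResponseMap(f, mxy[0], mz_out[0], meta=meta)
    return ResponseMap(f, mxy, mz_out, axis2_name="set_angle_deg", axis2=angles,
                       meta=meta)
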