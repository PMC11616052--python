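"""Off-resonant binomial water-excitation pulses.

Builds the LIBOR / LIBRE / BORR family of fat-suppressing excitation pulses,
plus the conventional on-resonant binomial and plain rectangular comparators,
as piecewise-constant RF waveforms.

All members of the family are a pair of back-to-back rectangular subpulses
transmitted at a frequency offset ``f_rf`` from water, distinguished only by
the phase relationship between the two subpulses:

====================  =================================================
pulse                 second-subpulse phase offset
====================  =================================================
LIBOR                 free parameter ``delta_phi`` (tuned for fat null)
LIBRE                 water-tracking offset ``(-360 f_rf tau) mod 360``
BORR                  fixed 180 deg
====================  =================================================

Phase convention
----------------
Subpulse phases are *carrier-referenced*: they are offsets relative to the
transmit carrier, which runs continuously at ``freq_offset`` for the whole
pulse (as on a scanner, where the synthesizer never resets between
subpulses).  Positive off-resonance precesses counter-clockwise about +z.
The LIBRE offset above is the phase that tracks the precessing water
magnetization between subpulses in this convention; literature that states
it as ``+2*pi*tau*f_rf`` uses the mirrored phase-sign convention.

Amplitudes are expressed as nutation frequency gamma*B1/(2*pi) in Hz.  The
"set" excitation angle follows the envelope convention used on scanner
consoles: ``set_angle = 360 * sum(amplitude_i * duration_i)`` degrees, so a
1 ms pulse set to 12 deg has a 33.33 Hz amplitude.  For off-resonant pulses
the actual rotation of the water magnetization (the *nominal* angle) is
smaller than the set angle; see :func:`wexsim.bloch.water_rotation_angle`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RFSegment",
    "RFPulse",
    "make_libor",
    "make_libre",
    "make_borr",
    "make_binomial",
    "make_rect",
    "libre_phase_offset",
    "rf_energy",
    "sample_waveform",
]


class ParameterError(ValueError):
    """Invalid pulse or sequence parameter."""


@dataclass(frozen=True)
class RFSegment:
    """One piecewise-constant RF segment.

    Parameters
    ----------
    amplitude : float
        Nutation frequency gamma*B1/(2*pi) in Hz, >= 0.
    freq_offset : float
        Transmit frequency relative to water in Hz.
    phase : float
        Carrier-referenced phase in degrees; stored modulo 360.
    duration : float
        Segment duration in seconds, > 0.
    """

    amplitude: float
    freq_offset: float
    phase: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError(f"segment duration must be > 0, got {self.duration}")
        if self.amplitude < 0:
            raise ParameterError(f"segment amplitude must be >= 0, got {self.amplitude}")
        object.__setattr__(self, "phase", float(self.phase) % 360.0)


@dataclass(frozen=True)
class RFPulse:
    """An ordered list of RF segments with a label and set excitation angle."""

    name: str
    segments: tuple[RFSegment, ...]
    set_angle: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ParameterError("pulse must contain at least one segment")
        if self.set_angle is None:
            object.__setattr__(self, "set_angle", self._envelope_angle())
        elif abs(self.set_angle - self._envelope_angle()) > 1e-6:
            raise ParameterError(
                f"set_angle {self.set_angle} inconsistent with envelope angle "
                f"{self._envelope_angle():.6f}"
            )

    def _envelope_angle(self) -> float:
        return 360.0 * sum(s.amplitude * s.duration for s in self.segments)

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def scaled(self, set_angle: float) -> "RFPulse":
        """Same waveform timing/phases with amplitudes rescaled to ``set_angle``."""
        if set_angle < 0:
            raise ParameterError("set_angle must be >= 0")
        cur = self.set_angle
        if cur == 0:
            raise ParameterError("cannot rescale a zero-amplitude pulse")
        k = set_angle / cur
        segs = tuple(replace(s, amplitude=s.amplitude * k) for s in self.segments)
        return RFPulse(self.name, segs, set_angle)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "set_angle_deg": self.set_angle,
            "segments": [
                {
                    "amplitude_hz": s.amplitude,
                    "freq_offset_hz": s.freq_offset,
                    "phase_deg": s.phase,
                    "duration_s": s.duration,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RFPulse":
        segs = tuple(
            RFSegment(
                amplitude=s["amplitude_hz"],
                freq_offset=s["freq_offset_hz"],
                phase=s["phase_deg"],
                duration=s["duration_s"],
            )
            for s in d["segments"]
        )
        return cls(d["name"], segs, d.get("set_angle_deg"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "RFPulse":
        return cls.from_dict(json.loads(s))


def _two_subpulses(
    name: str, tau: float, f_rf: float, delta_phi: float, set_angle: float
) -> RFPulse:
    if tau <= 0:
        raise ParameterError(f"subpulse duration must be > 0, got {tau}")
    if set_angle < 0:
        raise ParameterError(f"set_angle must be >= 0, got {set_angle}")
    amp = set_angle / (360.0 * 2.0 * tau)
    segs = (
        RFSegment(amp, f_rf, 0.0, tau),
        RFSegment(amp, f_rf, delta_phi, tau),
    )
    return RFPulse(name, segs, set_angle)


def make_libor(tau: float, f_rf: float, delta_phi: float, set_angle: float) -> RFPulse:
    """Lipid-insensitive binomial off-resonant (LIBOR) pulse.

    Two rectangular subpulses of duration ``tau`` (s) each, both transmitted
    at ``f_rf`` (Hz) off water, the second with a free phase offset
    ``delta_phi`` (deg).  The published 3T design is tau=500 us, f_rf=780 Hz,
    delta_phi around -45..-40 deg (i.e. 315..320), which places a wide
    stopband on the fat resonance at -440 Hz.
    """
    return _two_subpulses("LIBOR", tau, f_rf, delta_phi, set_angle)


def libre_phase_offset(tau: float, f_rf: float) -> float:
    """LIBRE second-subpulse phase offset in this package's convention.

    The LIBRE design phases the second subpulse to track the water
    magnetization that precessed (at approximately -f_rf relative to the
    carrier) during the first subpulse: ``(-360*tau*f_rf) mod 360`` degrees.
    The magnitude equals the usual ``2*pi*tau*f_rf`` statement; the sign is
    fixed by the carrier-referenced, right-handed phase convention used here.
    """
    return (-360.0 * tau * f_rf) % 360.0


def make_libre(tau: float, f_rf: float, set_angle: float) -> RFPulse:
    """Lipid-insensitive binomial off-resonant excitation (LIBRE) pulse.

    A LIBOR with the phase offset fixed to the water-tracking value
    :func:`libre_phase_offset`.  Published 3T designs: 2x500 us at 1620 Hz
    (1 ms) and 2x1100 us at 520 Hz (2.2 ms).
    """
    p = _two_subpulses("LIBRE", tau, f_rf, libre_phase_offset(tau, f_rf), set_angle)
    return p


def make_borr(tau: float, f_rf: float, set_angle: float) -> RFPulse:
    """Binomial off-resonant rectangular (BORR) pulse: LIBOR with a 180 deg offset."""
    return _two_subpulses("BORR", tau, f_rf, 180.0, set_angle)


def make_binomial(
    subpulse_tau: float, gap: float, phase_increment: float, set_angle: float
) -> RFPulse:
    """Conventional on-resonant binomial water-excitation pulse (e.g. 1-90-1).

    Two on-resonant rectangular subpulses with an optional silent gap and a
    phase increment on the second subpulse.  With zero gap and a +90 deg
    increment the 2x500 us version is the short water-excitation comparator
    whose stopband falls on the fat side (negative off-resonance) in this
    package's phase convention; a -90 deg increment mirrors the stopband to
    positive off-resonance.
    """
    if subpulse_tau <= 0:
        raise ParameterError(f"subpulse duration must be > 0, got {subpulse_tau}")
    if gap < 0:
        raise ParameterError(f"gap must be >= 0, got {gap}")
    if set_angle < 0:
        raise ParameterError(f"set_angle must be >= 0, got {set_angle}")
    amp = set_angle / (360.0 * 2.0 * subpulse_tau)
    segs = [RFSegment(amp, 0.0, 0.0, subpulse_tau)]
    if gap > 0:
        segs.append(RFSegment(0.0, 0.0, 0.0, gap))
    segs.append(RFSegment(amp, 0.0, phase_increment, subpulse_tau))
    return RFPulse("binomial", tuple(segs), set_angle)


def make_rect(duration: float, set_angle: float, freq_offset: float = 0.0) -> RFPulse:
    """Plain rectangular pulse (single segment)."""
    if duration <= 0:
        raise ParameterError(f"duration must be > 0, got {duration}")
    if set_angle < 0:
        raise ParameterError(f"set_angle must be >= 0, got {set_angle}")
    amp = set_angle / (360.0 * duration)
    return RFPulse("rect", (RFSegment(amp, freq_offset, 0.0, duration),), set_angle)


def rf_energy(pulse: RFPulse) -> float:
    """Relative RF energy integral sum(amplitude^2 * duration), in Hz^2*s.

    Proportional to the deposited RF energy (SAR is proportional to the time
    integral of B1 squared); only ratios between pulses are meaningful, no
    hardware calibration to W/kg is attempted.
    """
    if not pulse.segments:
        raise ParameterError("empty pulse")
    return sum(s.amplitude**2 * s.duration for s in pulse.segments)


def sample_waveform(pulse: RFPulse, raster: float = 1e-6) -> pd.DataFrame:
    """Sample the waveform on a uniform raster for plotting/export.

    Returns a DataFrame with columns ``time_s``, ``amplitude_hz``,
    ``freq_offset_hz`` and ``phase_deg``.  ``phase_deg`` is the B1 phase in
    the water rotating frame (carrier ramp ``360*freq_offset*t`` plus the
    segment's carrier-referenced phase), the quantity whose slope is f_rf in
    waveform plots.
    """
    if raster <= 0:
        raise ParameterError("raster must be > 0")
    rows = []
    t0 = 0.0
    for seg in pulse.segments:
        n = max(1, int(round(seg.duration / raster)))
        t_local = np.arange(n) * raster
        t = t0 + t_local
        phase = (seg.phase + 360.0 * seg.freq_offset * t) % 360.0
        rows.append(
            pd.DataFrame(
                {
                    "time_s": t,
                    "amplitude_hz": seg.amplitude,
                    "freq_offset_hz": seg.freq_offset,
                    "phase_deg": phase,
                }
            )
        )
        t0 += seg.duration
    return pd.concat(rows, ignore_index=True)
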