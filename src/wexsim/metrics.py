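"""Figures of merit: suppression bandwidth, optimum selection, SNR/CNR.

The central quantity is the *suppression band*: the contiguous off-resonance
interval, containing the fat resonance, where the post-excitation |Mxy|
falls to or below a fraction (default 10%) of a reference maximum.  The
reference defaults to the profile's own maximum; for a profile taken out of
a larger sweep, pass the sweep's maximum as ``reference`` so that all
profiles of one experiment share the "maximum observed |Mxy|" threshold.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bloch import FAT_FREQ_3T, ResponseMap, required_set_angle
from .pulses import ParameterError, RFPulse

__all__ = [
    "SuppressionBand",
    "RoiStats",
    "suppression_band",
    "band_table",
    "optimal_phase",
    "optimal_frequency",
    "water_efficiency",
    "roi_stats",
    "snr",
    "cnr",
]


class UndefinedValueError(ArithmeticError):
    """A ratio statistic is undefined (zero noise estimate)."""


@dataclass(frozen=True)
class SuppressionBand:
    """A contiguous sub-threshold stopband anchored at the fat resonance.

    ``truncated_low``/``truncated_high`` flag bands that reach the edge of
    the simulated grid: their true width is unknown (the measured width is a
    lower bound).
    """

    low: float
    high: float
    threshold_fraction: float
    anchor: float
    threshold: float
    truncated_low: bool = False
    truncated_high: bool = False

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def truncated(self) -> bool:
        return self.truncated_low or self.truncated_high

    def to_dict(self) -> dict:
        return {
            "low_hz": self.low,
            "high_hz": self.high,
            "width_hz": self.width,
            "threshold_fraction": self.threshold_fraction,
            "threshold": self.threshold,
            "anchor_hz": self.anchor,
            "truncated": self.truncated,
        }


def suppression_band(
    profile: ResponseMap,
    threshold_fraction: float = 0.10,
    anchor: float = FAT_FREQ_3T,
    reference: float | None = None,
) -> SuppressionBand:
    """Fat-anchored stopband of a 1-D frequency profile.

    The threshold is ``threshold_fraction * reference`` where ``reference``
    defaults to ``max(profile.mxy)``.  Returns the maximal contiguous run of
    grid points with |Mxy| <= threshold containing the grid point nearest to
    ``anchor``; if that point is above threshold, a zero-width band at the
    anchor is returned.
    """
    if profile.is_2d:
        raise ParameterError("suppression_band requires a 1-D profile")
    f, v = profile.freq, profile.mxy
    if f.size == 0:
        raise ParameterError("empty profile")
    if not (f[0] <= anchor <= f[-1]):
        raise ParameterError(f"anchor {anchor} Hz outside grid [{f[0]}, {f[-1]}]")
    ref = float(np.max(v)) if reference is None else float(reference)
    thr = threshold_fraction * ref
    sub = v <= thr
    i = int(np.argmin(np.abs(f - anchor)))
    if not sub[i]:
        return SuppressionBand(anchor, anchor, threshold_fraction, anchor, thr)
    lo = i
    while lo > 0 and sub[lo - 1]:
        lo -= 1
    hi = i
    while hi < f.size - 1 and sub[hi + 1]:
        hi += 1
    return SuppressionBand(
        float(f[lo]),
        float(f[hi]),
        threshold_fraction,
        anchor,
        thr,
        truncated_low=(lo == 0),
        truncated_high=(hi == f.size - 1),
    )


def band_table(
    sweep: ResponseMap,
    threshold_fraction: float = 0.10,
    anchor: float = FAT_FREQ_3T,
    shared_reference: bool = True,
) -> pd.DataFrame:
    """Per-row stopband summary of a 2-D sweep.

    With ``shared_reference`` (default) the threshold references the maximum
    |Mxy| observed anywhere in the sweep, as in the published band criterion;
    otherwise each row uses its own maximum.
    """
    if not sweep.is_2d:
        raise ParameterError("band_table requires a 2-D map")
    ref = float(np.max(sweep.mxy)) if shared_reference else None
    rows = []
    for i, val in enumerate(sweep.axis2):
        prof = ResponseMap(sweep.freq, sweep.mxy[i])
        b = suppression_band(prof, threshold_fraction, anchor, reference=ref)
        rows.append(
            {
                sweep.axis2_name or "axis2": float(val),
                "band_low_hz": b.low,
                "band_high_hz": b.high,
                "width_hz": b.width,
                "truncated": b.truncated,
                "water_mxy": float(np.interp(0.0, sweep.freq, sweep.mxy[i])),
            }
        )
    return pd.DataFrame(rows)


def optimal_phase(
    sweep: ResponseMap,
    threshold_fraction: float = 0.10,
    anchor: float = FAT_FREQ_3T,
    exclude_truncated: bool = True,
) -> float:
    """Phase modulation maximizing the anchored stopband width.

    Bands clipped by the edge of the simulated frequency grid have unknowable
    true width; with ``exclude_truncated`` (default) they are not eligible as
    the optimum (unless every nonzero band is truncated).  Ties are broken
    toward the band center nearest the anchor, then toward the smaller phase.
    """
    tab = band_table(sweep, threshold_fraction, anchor, shared_reference=True)
    widths = tab["width_hz"].to_numpy()
    eligible = np.ones(len(tab), bool)
    if exclude_truncated and (~tab["truncated"] & (widths > 0)).any():
        eligible = ~tab["truncated"].to_numpy()
    w = np.where(eligible, widths, -1.0)
    best = w.max()
    idx = np.flatnonzero(w == best)
    centers = 0.5 * (tab["band_low_hz"] + tab["band_high_hz"]).to_numpy()[idx]
    idx = idx[np.abs(centers - anchor) == np.min(np.abs(centers - anchor))]
    phases = tab.iloc[:, 0].to_numpy()
    return float(phases[idx].min())


def optimal_frequency(
    profiles: Mapping[float, ResponseMap],
    objective: str | Callable[[ResponseMap], float] = "band_width",
    threshold_fraction: float = 0.10,
    anchor: float = FAT_FREQ_3T,
) -> float:
    """Excitation frequency maximizing an objective over calibration profiles.

    ``profiles`` maps the candidate f_rf (Hz) to its simulated 1-D profile.
    ``objective`` is ``"band_width"`` (anchored stopband width, shared
    threshold reference across candidates) or any callable scoring a profile
    (e.g. a phantom-based water-fat CNR).  Ties go to the smaller frequency.
    """
    if not profiles:
        raise ParameterError("no profiles supplied")
    freqs = sorted(profiles)
    if callable(objective):
        scores = {f: objective(profiles[f]) for f in freqs}
    elif objective == "band_width":
        ref = max(float(np.max(profiles[f].mxy)) for f in freqs)
        scores = {
            f: suppression_band(profiles[f], threshold_fraction, anchor, ref).width
            for f in freqs
        }
    else:
        raise ParameterError(f"unknown objective {objective!r}")
    best = max(scores.values())
    return float(min(f for f in freqs if scores[f] == best))


def water_efficiency(
    pulse_factory: Callable[[float], RFPulse],
    nominal: float,
    resolution: float = 1.0,
) -> float:
    """Water-excitation efficiency: nominal angle / required set angle.

    Equals 1 for on-resonant pulses and drops below 1 as the transmit offset
    makes water excitation less effective (the set angle, hence the RF power,
    must rise to reach the same water rotation).
    """
    return nominal / required_set_angle(pulse_factory, nominal, resolution)


@dataclass(frozen=True)
class RoiStats:
    """Mean/SD signal statistics of a region of interest."""

    mean: float
    sd: float
    count: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ParameterError("ROI must contain at least one pixel")
        if self.sd < 0:
            raise ParameterError("SD must be >= 0")


def roi_stats(image: np.ndarray, mask: np.ndarray, label: str = "") -> RoiStats:
    """Population-SD statistics of the pixels selected by a boolean mask."""
    vals = np.asarray(image)[np.asarray(mask, bool)]
    if vals.size == 0:
        raise ParameterError(f"ROI {label!r} selects no pixels")
    return RoiStats(float(vals.mean()), float(vals.std()), int(vals.size), label)


def snr(roi: RoiStats, background: RoiStats) -> float:
    """Signal-to-noise ratio: ROI mean over background SD."""
    if background.sd == 0:
        raise UndefinedValueError("background SD is zero; SNR undefined")
    return roi.mean / background.sd


def cnr(roi_a: RoiStats, roi_b: RoiStats, background: RoiStats) -> float:
    """Contrast-to-noise ratio: SNR(a) - SNR(b); antisymmetric in (a, b)."""
    return snr(roi_a, background) - snr(roi_b, background)
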