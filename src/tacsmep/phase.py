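"""Instantaneous-phase estimation of the tACS monitor channel.

The tACS current is commanded at a known frequency, so the phase at each
TMS pulse is estimated parametrically: a least-squares sinusoid
``A * cos(2*pi*f*t + phi) + c`` is fitted to a short window of the
monitored oscillation ending just before the pulse and extrapolated to
the pulse sample.  This is more robust near stimulation artifacts than a
Hilbert transform, which needs artifact-free data on both sides of the
pulse.

Phase convention: 0 deg is the positive peak of the commanded tACS
current, phase increases with time, so 90 deg is the falling edge,
180 deg the trough and 270 deg the rising edge.  The four quadrant bins
are centred on those angles with half-open boundaries at +-45 deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io import SessionRecording

__all__ = [
    "PhaseBin",
    "PhaseEstimate",
    "PolarityResult",
    "SinusoidFit",
    "classify_phase",
    "classify_phase_array",
    "check_polarity",
    "circular_difference_deg",
    "fit_sinusoid",
    "phase_at_pulse",
    "wrap_phase_deg",
]


class PhaseBin(Enum):
    """Quadrant of the oscillation cycle, named as in closed-loop TMS work."""

    PEAK = ("peak", 0.0)
    FALLING = ("falling", 90.0)
    TROUGH = ("trough", 180.0)
    RISING = ("rising", 270.0)

    def __init__(self, label: str, center_deg: float):
        self.label = label
        self.center_deg = center_deg

    @classmethod
    def from_label(cls, label: str) -> "PhaseBin":
        for b in cls:
            if b.label == label:
                return b
        raise ValueError(f"unknown phase bin label {label!r}")


#: Bin order used in all tabular outputs.
BIN_ORDER = tuple(b.label for b in PhaseBin)


def wrap_phase_deg(phase_deg):
    """Wrap angles into [0, 360)."""
    return np.asarray(phase_deg, dtype=float) % 360.0


def circular_difference_deg(a, b):
    """Signed circular difference a - b in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def classify_phase(phase_deg: float) -> PhaseBin:
    """Assign a phase angle to its quadrant bin.

    Bins are half-open quadrants centred on the nominal angles:
    peak [315, 360) u [0, 45), falling [45, 135), trough [135, 225),
    rising [225, 315).  Total on the real line (angles are wrapped).
    """
    idx = int((float(phase_deg) % 360.0 + 45.0) // 90.0) % 4
    return list(PhaseBin)[idx]


def classify_phase_array(phase_deg) -> np.ndarray:
    """Vectorised :func:`classify_phase`; returns an array of bin labels."""
    idx = (((np.asarray(phase_deg, dtype=float) % 360.0 + 45.0) // 90.0) % 4).astype(int)
    return np.asarray(BIN_ORDER, dtype=object)[idx]


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares fit of ``A*cos(2*pi*f*t + phi) + c`` to a segment."""

    amplitude: float
    phase_offset_deg: float  # phi at the first sample of the segment
    offset: float
    r2: float
    frequency: float


@dataclass(frozen=True)
class PhaseEstimate:
    """Estimated tACS phase at one TMS pulse."""

    pulse_index: int
    phase_deg: float
    fit_r2: float
    reversed: bool

    def __post_init__(self):
        if not (0.0 <= self.phase_deg < 360.0):
            raise ValueError("phase_deg must lie in [0, 360)")
        if not (0.0 <= self.fit_r2 <= 1.0):
            raise ValueError("fit_r2 must lie in [0, 1]")


@dataclass(frozen=True)
class PolarityResult:
    reversed: bool
    fit_r2: float
    ambiguous: bool
    phase_at_onset_deg: float


class SegmentError(ValueError):
    """Segment unsuitable for sinusoid fitting (too short / zero variance)."""


class WindowUnavailableError(ValueError):
    """No artifact-free fit window exists before the pulse."""


def fit_sinusoid(segment, frequency: float, sampling_rate: float) -> SinusoidFit:
    """Fit ``A*cos(2*pi*f*t + phi) + c`` with t = 0 at the first sample.

    The frequency is known (commanded), so the fit is linear in
    ``(A*cos(phi), -A*sin(phi), c)`` and solved in closed form.  Returns
    A >= 0 with phi normalised to [0, 360).

    Raises :class:`SegmentError` if the segment spans fewer than two full
    cycles or has zero variance.
    """
    y = np.asarray(segment, dtype=float)
    if y.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    if frequency <= 0 or sampling_rate <= 0:
        raise ValueError("frequency and sampling_rate must be positive")
    if y.size < int(np.ceil(2.0 * sampling_rate / frequency)):
        raise SegmentError(
            f"segment of {y.size} samples spans < 2 cycles at {frequency} Hz"
        )
    if np.ptp(y) == 0.0:
        raise SegmentError("zero-variance segment")

    t = np.arange(y.size) / sampling_rate
    w = 2.0 * np.pi * frequency * t
    design = np.column_stack([np.cos(w), np.sin(w), np.ones_like(w)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b, c = coef
    amplitude = float(np.hypot(a, b))
    # y = a*cos(wt) + b*sin(wt) = A*cos(wt + phi) with phi = atan2(-b, a)
    phi = float(np.degrees(np.arctan2(-b, a)) % 360.0)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return SinusoidFit(amplitude, phi, float(c), max(0.0, min(1.0, r2)), frequency)


def check_polarity(
    recording: "SessionRecording",
    *,
    fit_duration_s: float = 5.0,
    min_r2: float = 0.5,
) -> PolarityResult:
    """Decide whether the monitored tACS waveform is inverted.

    The commanded current starts at phase 0 (positive peak) at
    ``recording.tacs_onset_sample``.  A sinusoid is fitted to the first
    ``fit_duration_s`` seconds from onset; if the fitted phase at onset
    is closer to 180 deg than to 0 deg the montage recorded the current
    inverted and all estimated phases must be shifted by 180 deg.

    If the fit explains too little variance (``r2 < min_r2``) polarity is
    ambiguous: a warning is issued and no correction is applied.
    """
    fs = recording.sampling_rate
    f = recording.tacs_frequency
    start = int(recording.tacs_onset_sample)
    n = int(round(fit_duration_s * fs))
    if recording.tacs_monitor.size - start < n:
        raise SegmentError(
            f"need >= {fit_duration_s} s of monitor signal after tACS onset"
        )
    fit = fit_sinusoid(recording.tacs_monitor[start : start + n], f, fs)
    phase_at_onset = fit.phase_offset_deg
    if fit.r2 < min_r2:
        warnings.warn(
            f"ambiguous tACS monitor polarity (fit r2 = {fit.r2:.3f} < {min_r2}); "
            "no phase-reversal correction applied",
            RuntimeWarning,
            stacklevel=2,
        )
        return PolarityResult(False, fit.r2, True, phase_at_onset)
    inverted = abs(circular_difference_deg(phase_at_onset, 0.0)) > 90.0
    return PolarityResult(bool(inverted), fit.r2, False, phase_at_onset)


def phase_at_pulse(
    recording: "SessionRecording",
    pulse_index: int,
    *,
    window_cycles: int = 3,
    gap_ms: float = 5.0,
    reversed: bool = False,
    reversal_shift_deg: float = 180.0,
) -> PhaseEstimate:
    """Estimate the tACS phase at a TMS pulse sample.

    A window of ``window_cycles`` full cycles ending ``gap_ms`` before the
    pulse (to stay clear of the stimulation artifact) is fitted and the
    sinusoid extrapolated to the pulse sample.  ``reversed`` applies the
    polarity correction determined by :func:`check_polarity`;
    ``reversal_shift_deg`` is 180 for a sign inversion of the monitored
    waveform (default) or 90 for a sine/cosine convention shift.

    Raises :class:`WindowUnavailableError` when the pulse is too early in
    the recording for a full fit window; callers flag such trials as
    unphased and exclude them.
    """
    fs = recording.sampling_rate
    f = recording.tacs_frequency
    gap = int(round(gap_ms * fs / 1000.0))
    n_win = int(round(window_cycles * fs / f))
    end = int(pulse_index) - gap
    start = end - n_win
    if start < 0:
        raise WindowUnavailableError(
            f"pulse at sample {pulse_index} has no {window_cycles}-cycle "
            f"fit window ending {gap_ms} ms before it"
        )
    fit = fit_sinusoid(recording.tacs_monitor[start:end], f, fs)
    phase = (fit.phase_offset_deg + 360.0 * f * (pulse_index - start) / fs) % 360.0
    if reversed:
        phase = (phase + reversal_shift_deg) % 360.0
    return PhaseEstimate(int(pulse_index), float(phase), fit.r2, bool(reversed))
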