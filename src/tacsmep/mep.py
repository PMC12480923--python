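"""Trial rejection, MEP quantification and per-phase summaries.

The rejection rule follows the pre-stimulus quiescence criterion used in
single-pulse TMS work: a trial is excluded when the EMG excursion in the
500 ms window preceding the pulse exceeds 50 uV (muscle pre-contraction
or noise).  The criterion is applied to the window before the *pulse*
rather than before MEP onset — the two differ by the ~20 ms MEP latency,
which is immaterial for a quiescence check, and the pulse sample is
unambiguous.  Rejection is causal: it never looks at post-pulse samples.

MEP size is the peak-to-peak EMG amplitude in a 15-55 ms post-pulse
search window, which spans FDI MEP latencies while excluding the
stimulation artifact.

Per participant and phase bin the summaries are: the median accepted
amplitude, its z-score across the participant's four bin medians
(mean 0, SD 1 within participant — so group means across participants
sum to ~0 by construction), and the coefficient of variation
(sample SD / mean of the raw accepted amplitudes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phase import BIN_ORDER

__all__ = [
    "InsufficientWindowError",
    "reject_precontraction",
    "mep_amplitude",
    "summarize_bins",
    "count_pulses_per_bin",
    "coefficient_of_variation",
    "zscore_across_bins",
]

TRIAL_COLUMNS = (
    "participant",
    "session",
    "tacs_frequency",
    "pulse_index",
    "time_s",
    "phase_deg",
    "fit_r2",
    "bin",
    "mep_amplitude",
    "rejected",
    "rejection_reason",
)

SUMMARY_COLUMNS = (
    "participant",
    "session",
    "tacs_frequency",
    "bin",
    "n_trials",
    "median_mep",
    "z_median",
    "cv",
    "degenerate",
)


class InsufficientWindowError(ValueError):
    """The requested analysis window does not fit inside the recording."""


def reject_precontraction(
    emg,
    pulse_index: int,
    sampling_rate: float,
    *,
    window_ms: float = 500.0,
    threshold_uv: float = 50.0,
    measure: str = "ptp",
) -> bool:
    """True iff the pre-pulse EMG window shows pre-contraction or noise.

    Examines ``[pulse - window_ms, pulse)``.  ``measure`` selects how
    "exceeds threshold" is read: peak-to-peak excursion (default) or
    maximum absolute value (``"abs"``).

    Raises :class:`InsufficientWindowError` when fewer than ``window_ms``
    of EMG precede the pulse.
    """
    emg = np.asarray(emg, dtype=float)
    n_win = int(round(window_ms * sampling_rate / 1000.0))
    start = int(pulse_index) - n_win
    if start < 0:
        raise InsufficientWindowError(
            f"pulse at sample {pulse_index} lacks a {window_ms} ms pre-pulse window"
        )
    window = emg[start : int(pulse_index)]
    if measure == "ptp":
        excursion = float(np.ptp(window))
    elif measure == "abs":
        excursion = float(np.max(np.abs(window)))
    else:
        raise ValueError("measure must be 'ptp' or 'abs'")
    return excursion > threshold_uv


def mep_amplitude(
    emg,
    pulse_index: int,
    sampling_rate: float,
    *,
    search_window_ms: tuple = (15.0, 55.0),
    artifact_blank_ms: float = 5.0,
) -> float:
    """Peak-to-peak EMG amplitude in the post-pulse MEP search window.

    The window is ``[pulse + search_window_ms[0], pulse +
    search_window_ms[1]]``; its start is additionally clamped past the
    ``artifact_blank_ms`` blanking period.  Raises
    :class:`InsufficientWindowError` when the window extends past the
    end of the recording.
    """
    emg = np.asarray(emg, dtype=float)
    fs = sampling_rate
    lo = int(pulse_index) + max(
        int(round(search_window_ms[0] * fs / 1000.0)),
        int(round(artifact_blank_ms * fs / 1000.0)),
    )
    hi = int(pulse_index) + int(round(search_window_ms[1] * fs / 1000.0)) + 1
    if hi > emg.size:
        raise InsufficientWindowError(
            f"MEP window for pulse at sample {pulse_index} extends past the recording"
        )
    return float(np.ptp(emg[lo:hi]))


def coefficient_of_variation(values, axis=None, ddof: int = 1):
    """SD/mean with the sample (n-1) denominator; NaN-aware."""
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nanstd(values, axis=axis, ddof=ddof) / np.nanmean(values, axis=axis)


def zscore_across_bins(medians, axis=-1, ddof: int = 1):
    """Z-score a set of bin medians within participant (mean 0, SD 1).

    Returns NaN for every entry when the SD along ``axis`` is zero or
    any median is missing — the four-bin z-profile is only defined for
    participants with all bins populated and non-degenerate.
    """
    medians = np.asarray(medians, dtype=float)
    mean = medians.mean(axis=axis, keepdims=True)
    sd = medians.std(axis=axis, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (medians - mean) / sd
    return np.where(np.broadcast_to(sd, z.shape) > 0, z, np.nan)


def summarize_bins(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x session x phase bin summary of accepted trials.

    Input is a trial table with at least the columns participant,
    session, tacs_frequency, bin, mep_amplitude, rejected.  For each of
    the four bins the summary carries the accepted-trial count, median
    amplitude, within-participant z-scored median and CV.  Empty bins
    yield n_trials = 0 with NaN statistics; a participant-session with
    any empty or zero-variance bin has NaN z-scores and is flagged
    ``degenerate`` (such participants are excluded from group z
    analyses).  CV needs >= 2 accepted trials.
    """
    rows = []
    for (pid, sess, freq), group in trials.groupby(
        ["participant", "session", "tacs_frequency"], sort=True
    ):
        accepted = group[~group["rejected"]]
        medians = np.full(4, np.nan)
        for b, label in enumerate(BIN_ORDER):
            amps = accepted.loc[accepted["bin"] == label, "mep_amplitude"].to_numpy()
            medians[b] = np.median(amps) if amps.size else np.nan
        z = zscore_across_bins(medians) if not np.isnan(medians).any() else np.full(4, np.nan)
        degenerate = bool(np.isnan(z).any())
        for b, label in enumerate(BIN_ORDER):
            amps = accepted.loc[accepted["bin"] == label, "mep_amplitude"].to_numpy()
            rows.append(
                {
                    "participant": pid,
                    "session": sess,
                    "tacs_frequency": freq,
                    "bin": label,
                    "n_trials": int(amps.size),
                    "median_mep": medians[b],
                    "z_median": z[b],
                    "cv": float(coefficient_of_variation(amps)) if amps.size >= 2 else np.nan,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def count_pulses_per_bin(trials: pd.DataFrame) -> pd.DataFrame:
    """Accepted-trial counts per phase bin and session, with group means.

    One row per participant-session plus a ``group-mean`` row per
    session label; columns are the four bins in cycle order.
    """
    accepted = trials[~trials["rejected"]]
    counts = (
        accepted.groupby(["session", "participant", "bin"], sort=True)
        .size()
        .unstack("bin", fill_value=0)
        .reindex(columns=list(BIN_ORDER), fill_value=0)
    )
    # participant-sessions whose trials were all rejected still get a zero row
    all_pairs = trials[["session", "participant"]].drop_duplicates()
    counts = counts.reindex(
        pd.MultiIndex.from_frame(all_pairs).sortlevel()[0], fill_value=0
    )
    out = counts.reset_index()
    means = (
        counts.groupby(level="session").mean().reset_index().assign(participant="group-mean")
    )
    return pd.concat([out, means], ignore_index=True)[
        ["session", "participant", *BIN_ORDER]
    ]
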