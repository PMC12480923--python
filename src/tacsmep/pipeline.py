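"""End-to-end session analysis: recording -> trial table -> summaries."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io import SessionRecording
from .mep import (
    InsufficientWindowError,
    TRIAL_COLUMNS,
    mep_amplitude,
    reject_precontraction,
    summarize_bins,
)
from .phase import (
    SegmentError,
    WindowUnavailableError,
    check_polarity,
    classify_phase,
    phase_at_pulse,
)
from .stats import GroupResult, group_summary

__all__ = ["AnalysisConfig", "analyze_session", "analyze_cohort", "run_group_analysis"]


@dataclass
class AnalysisConfig:
    """All analysis thresholds and windows in one place.

    Defaults: 500 ms / 50 uV peak-to-peak pre-contraction rejection,
    15-55 ms MEP search window with a 5 ms artifact blank, 3-cycle
    sinusoid-fit window ending 5 ms before the pulse, minimum fit r2 of
    0.8 for a trial to be phased, and a 180 deg shift when the monitor
    polarity is reversed.
    """

    precontraction_window_ms: float = 500.0
    precontraction_threshold_uv: float = 50.0
    precontraction_measure: str = "ptp"  # or "abs"
    mep_window_ms: tuple = (15.0, 55.0)
    artifact_blank_ms: float = 5.0
    fit_window_cycles: int = 3
    fit_gap_ms: float = 5.0
    min_fit_r2: float = 0.8
    polarity_min_r2: float = 0.5
    polarity_fit_duration_s: float = 5.0
    reversal_shift_deg: float = 180.0
    #: montage-dependent override: None = detect from the monitor signal,
    #: True/False = force the stated polarity (anode/cathode swap is a
    #: recording-setup fact, never auto-guessed when known).
    force_reversed: bool | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown analysis-config keys: {sorted(unknown)}")
        if "mep_window_ms" in raw:
            raw["mep_window_ms"] = tuple(raw["mep_window_ms"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def analyze_session(
    rec: SessionRecording, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Run the per-trial analysis of one session.

    Determines the monitor polarity once, then for every TMS pulse
    estimates the tACS phase (rejecting trials whose sinusoid fit is
    unavailable or poor as ``unphased``), applies the pre-contraction
    rejection, and measures the peak-to-peak MEP amplitude.  Returns the
    trial table (one row per pulse; no-pulse control events are not
    analysed).  Amplitudes are reported for rejected trials too when the
    window exists — rejection decides inclusion in summaries, not
    measurement.
    """
    cfg = cfg or AnalysisConfig()
    if rec.pulse_markers.size == 0:
        return pd.DataFrame(columns=list(TRIAL_COLUMNS))

    if cfg.force_reversed is not None:
        reversed_flag = bool(cfg.force_reversed)
    else:
        try:
            polarity = check_polarity(
                rec,
                fit_duration_s=cfg.polarity_fit_duration_s,
                min_r2=cfg.polarity_min_r2,
            )
            reversed_flag = polarity.reversed
        except SegmentError:
            reversed_flag = False

    rows = []
    for pulse in rec.pulse_markers:
        phase_deg = np.nan
        fit_r2 = np.nan
        label = None
        reason = "none"
        try:
            est = phase_at_pulse(
                rec,
                int(pulse),
                window_cycles=cfg.fit_window_cycles,
                gap_ms=cfg.fit_gap_ms,
                reversed=reversed_flag,
                reversal_shift_deg=cfg.reversal_shift_deg,
            )
            phase_deg, fit_r2 = est.phase_deg, est.fit_r2
            if fit_r2 < cfg.min_fit_r2:
                reason = "unphased"
            else:
                label = classify_phase(phase_deg).label
        except (WindowUnavailableError, SegmentError):
            reason = "unphased"

        if reason == "none":
            try:
                if reject_precontraction(
                    rec.emg,
                    int(pulse),
                    rec.sampling_rate,
                    window_ms=cfg.precontraction_window_ms,
                    threshold_uv=cfg.precontraction_threshold_uv,
                    measure=cfg.precontraction_measure,
                ):
                    reason = "precontraction"
            except InsufficientWindowError:
                reason = "window"

        try:
            amplitude = mep_amplitude(
                rec.emg,
                int(pulse),
                rec.sampling_rate,
                search_window_ms=cfg.mep_window_ms,
                artifact_blank_ms=cfg.artifact_blank_ms,
            )
        except InsufficientWindowError:
            amplitude = np.nan
            if reason == "none":
                reason = "window"

        rows.append(
            {
                "participant": rec.participant,
                "session": rec.session,
                "tacs_frequency": rec.tacs_frequency,
                "pulse_index": int(pulse),
                "time_s": pulse / rec.sampling_rate,
                "phase_deg": phase_deg,
                "fit_r2": fit_r2,
                "bin": label,
                "mep_amplitude": amplitude,
                "rejected": reason != "none",
                "rejection_reason": reason,
            }
        )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def analyze_cohort(
    sessions: Iterable[SessionRecording], cfg: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse many sessions; returns (all trials, per-bin summaries)."""
    cfg = cfg or AnalysisConfig()
    tables = [analyze_session(rec, cfg) for rec in sessions]
    trials = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=list(TRIAL_COLUMNS))
    )
    return trials, summarize_bins(trials)


def run_group_analysis(bin_summaries: pd.DataFrame) -> dict[str, GroupResult]:
    """Group aggregation per session label (alpha / beta)."""
    return {
        session: group_summary(sub)
        for session, sub in bin_summaries.groupby("session", sort=True)
    }
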