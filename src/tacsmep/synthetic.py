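"""Synthetic tACS+TMS sessions with known phase-dependent excitability.

The generator embodies a phenomenological ground-truth model so every
downstream stage (phase estimation, artifact rejection, MEP
quantification, group statistics) can be verified against a known
answer.  The noiseless peak-to-peak MEP amplitude of a trial delivered
at tACS phase ``theta`` is

    amplitude = baseline_mep * (1 + modulation_depth * cos(theta - preferred_phase))

and the rendered amplitude multiplies this by lognormal trial-to-trial
noise.  Pulses are scheduled at 4 +- 1 s intervals, snapped to their
target phase (0/90/180/270 deg, randomised order, Gaussian phase jitter)
on the commanded sinusoid, and randomly assigned to the TMS-pulse or
no-pulse control condition.  The EMG channel carries Gaussian baseline
noise, a 2 ms saturated stimulation artifact at each pulse, a biphasic
MEP waveform at 22 ms latency, and — on a random subset of trials — an
oscillatory pre-contraction burst in the 500 ms pre-pulse window.

The trial table produced by :func:`schedule_events` /
:func:`sample_trial_outcomes` is the generator's sampling layer; the
waveform renderer consumes it unchanged, so trial-level Monte-Carlo
experiments and full-signal sessions draw from exactly the same model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .io import SessionRecording

__all__ = [
    "GenerationConfig",
    "GroundTruth",
    "generate_session",
    "generate_cohort",
    "modulated_amplitude",
    "schedule_events",
    "sample_trial_outcomes",
]


@dataclass
class GenerationConfig:
    """Parameters of one synthetic participant-session.

    Units: frequencies in Hz, durations in s, phases in degrees,
    amplitudes in uV (EMG) or arbitrary units (tACS monitor).
    ``trial_noise`` is the sigma of the multiplicative lognormal
    trial-to-trial amplitude noise; sigma 0.5 yields coefficients of
    variation around 0.53, in the physiological range for single-pulse
    MEPs.  ``seed`` is mandatory: every session is reproducible.
    """

    seed: int
    tacs_frequency: float = 10.0
    tacs_monitor_amplitude: float = 1.0
    monitor_noise_sd: float = 0.0707  # a.u.; ~20 dB SNR at unit amplitude
    sampling_rate: float = 2000.0
    n_blocks: int = 4
    block_duration: float = 300.0
    iti_mean: float = 4.0
    iti_jitter: float = 1.0
    p_tms: float = 0.5
    phase_targets: tuple = (0.0, 90.0, 180.0, 270.0)
    phase_targeting_jitter_sd: float = 10.0
    baseline_mep: float = 1000.0
    modulation_depth: float = 0.3
    preferred_phase: float = 180.0
    trial_noise: float = 0.5
    emg_noise_sd: float = 5.0
    precontraction_rate: float = 0.05
    precontraction_amplitude: float = 100.0  # peak-to-peak, uV
    artifact_amplitude: float = 5000.0
    artifact_duration_ms: float = 2.0
    mep_latency_ms: float = 22.0
    mep_phase_durations_ms: tuple = (7.0, 8.0)
    monitor_inverted: bool = False
    participant: str = "SYN01"
    session: str = ""

    #: minimum quiet time a trial needs: 500 ms pre-pulse window plus the
    #: post-pulse MEP search window.
    _TRIAL_SPAN_S = 0.56

    def __post_init__(self):
        if self.sampling_rate <= 2.0 * self.tacs_frequency:
            raise ValueError("sampling_rate must exceed twice the tACS frequency")
        if not (0.0 <= self.modulation_depth < 1.0):
            raise ValueError("modulation_depth must lie in [0, 1)")
        if self.iti_mean - self.iti_jitter <= self._TRIAL_SPAN_S:
            raise ValueError(
                "iti_mean - iti_jitter must exceed the pre-window + MEP window span"
            )
        if not (0.0 <= self.precontraction_rate <= 1.0):
            raise ValueError("precontraction_rate must be a probability")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.session:
            self.session = "alpha" if self.tacs_frequency < 15 else "beta"

    @property
    def total_duration(self) -> float:
        return self.n_blocks * self.block_duration

    @classmethod
    def from_yaml(cls, path) -> "GenerationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown generation-config keys: {sorted(unknown)}")
        if "phase_targets" in raw:
            raw["phase_targets"] = tuple(raw["phase_targets"])
        if "mep_phase_durations_ms" in raw:
            raw["mep_phase_durations_ms"] = tuple(raw["mep_phase_durations_ms"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Hidden parameters and per-pulse ledger of a generated session.

    ``pulses`` has one row per scheduled event, with the commanded-phase
    convention (0 deg = positive current peak, regardless of monitor
    inversion): sample, time_s, block, kind (tms/control),
    target_phase_deg, true_phase_deg, mep_model_uv (noiseless model
    amplitude), mep_rendered_uv (after lognormal trial noise; what the
    EMG waveform actually carries), precontraction.
    """

    preferred_phase: float
    modulation_depth: float
    baseline_mep: float
    pulses: pd.DataFrame

    @property
    def tms_pulses(self) -> pd.DataFrame:
        return self.pulses[self.pulses["kind"] == "tms"].reset_index(drop=True)

    def write(self, path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"# preferred_phase_deg: {self.preferred_phase}\n")
            fh.write(f"# modulation_depth: {self.modulation_depth}\n")
            fh.write(f"# baseline_mep_uv: {self.baseline_mep}\n")
            self.pulses.to_csv(fh, sep="\t", index=False)
        return path

    @classmethod
    def read(cls, path) -> "GroundTruth":
        path = Path(path)
        meta = {}
        skip = 0
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = float(value)
        pulses = pd.read_csv(path, sep="\t", skiprows=skip)
        return cls(
            preferred_phase=meta["preferred_phase_deg"],
            modulation_depth=meta["modulation_depth"],
            baseline_mep=meta["baseline_mep_uv"],
            pulses=pulses,
        )


def modulated_amplitude(cfg: GenerationConfig, phase_deg) -> np.ndarray:
    """Noiseless peak-to-peak MEP amplitude of the ground-truth model."""
    delta = np.radians(np.asarray(phase_deg, dtype=float) - cfg.preferred_phase)
    return cfg.baseline_mep * (1.0 + cfg.modulation_depth * np.cos(delta))


def schedule_events(cfg: GenerationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Schedule pulse events: times, conditions and commanded phases.

    Events start 2 s into the recording (so a full pre-pulse window and
    sinusoid-fit window exist), advance by uniform 4 +- 1 s intervals,
    cycle through the four phase targets in randomised order with
    approximately equal counts, and are snapped to the nearest time at
    which the commanded sinusoid reaches the jittered target phase
    (shift at most half a cycle, negligible against the ITI).  The true
    phase is evaluated at the quantised sample index.
    """
    f, fs = cfg.tacs_frequency, cfg.sampling_rate
    times = []
    t = 2.0
    end = cfg.total_duration - 1.0
    while t < end:
        times.append(t)
        t += rng.uniform(cfg.iti_mean - cfg.iti_jitter, cfg.iti_mean + cfg.iti_jitter)
    n = len(times)

    targets = np.empty(n)
    bag: list = []
    for i in range(n):
        if not bag:
            bag = list(rng.permutation(cfg.phase_targets))
        targets[i] = bag.pop()
    jittered = targets + rng.normal(0.0, cfg.phase_targeting_jitter_sd, size=n)

    times = np.asarray(times)
    # nearest t' with 360*f*t' = jittered target (mod 360)
    frac = jittered / 360.0
    snapped = (np.round(times * f - frac) + frac) / f
    samples = np.round(snapped * fs).astype(int)
    true_phase = (360.0 * f * samples / fs) % 360.0

    kind = np.where(rng.random(n) < cfg.p_tms, "tms", "control")
    return pd.DataFrame(
        {
            "sample": samples,
            "time_s": samples / fs,
            "block": np.minimum(
                (samples / fs // cfg.block_duration).astype(int), cfg.n_blocks - 1
            ),
            "kind": kind,
            "target_phase_deg": targets % 360.0,
            "true_phase_deg": true_phase,
        }
    )


def sample_trial_outcomes(
    cfg: GenerationConfig, events: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-trial amplitudes and pre-contraction flags for TMS events."""
    events = events.copy()
    model = modulated_amplitude(cfg, events["true_phase_deg"].to_numpy())
    noise = rng.lognormal(0.0, cfg.trial_noise, size=len(events))
    is_tms = (events["kind"] == "tms").to_numpy()
    events["mep_model_uv"] = np.where(is_tms, model, np.nan)
    events["mep_rendered_uv"] = np.where(is_tms, model * noise, np.nan)
    events["precontraction"] = is_tms & (rng.random(len(events)) < cfg.precontraction_rate)
    return events


def _mep_template(cfg: GenerationConfig) -> np.ndarray:
    """Biphasic MEP waveform with unit peak-to-peak amplitude.

    Two half-sines (positive then negative, 7 + 8 ms by default, 0.6/0.4
    amplitude split) — a physiologically conventional shape; only the
    peak-to-peak amplitude matters downstream.
    """
    fs = cfg.sampling_rate
    n1 = int(round(cfg.mep_phase_durations_ms[0] * fs / 1000.0))
    n2 = int(round(cfg.mep_phase_durations_ms[1] * fs / 1000.0))
    pos = 0.6 * np.sin(np.pi * np.arange(n1) / n1)
    neg = -0.4 * np.sin(np.pi * np.arange(n2) / n2)
    return np.concatenate([pos, neg])


def generate_session(cfg: GenerationConfig) -> tuple[SessionRecording, GroundTruth]:
    """Render one complete synthetic session.

    Returns the recording (EMG + tACS monitor + markers) together with
    the ground-truth ledger.  Identical configs (same seed) produce
    bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    events = sample_trial_outcomes(cfg, schedule_events(cfg, rng), rng)

    fs = cfg.sampling_rate
    n = int(round(cfg.total_duration * fs))
    t = np.arange(n) / fs
    sign = -1.0 if cfg.monitor_inverted else 1.0
    monitor = sign * cfg.tacs_monitor_amplitude * np.cos(
        2.0 * np.pi * cfg.tacs_frequency * t
    )
    if cfg.monitor_noise_sd > 0:
        monitor = monitor + rng.normal(0.0, cfg.monitor_noise_sd, size=n)

    emg = rng.normal(0.0, cfg.emg_noise_sd, size=n) if cfg.emg_noise_sd > 0 else np.zeros(n)

    art_n = int(round(cfg.artifact_duration_ms * fs / 1000.0))
    lat_n = int(round(cfg.mep_latency_ms * fs / 1000.0))
    template = _mep_template(cfg)
    pre_n = int(round(0.5 * fs))

    tms = events[events["kind"] == "tms"]
    for row in tms.itertuples():
        i = int(row.sample)
        emg[i : i + art_n] = cfg.artifact_amplitude  # saturated transient
        start = i + lat_n
        emg[start : start + template.size] += row.mep_rendered_uv * template
        if row.precontraction:
            # 20 Hz burst, 300 ms, fully inside the 500 ms pre-pulse window
            b0 = i - pre_n + int(round(0.05 * fs))
            bn = int(round(0.3 * fs))
            tb = np.arange(bn) / fs
            burst = (
                0.5
                * cfg.precontraction_amplitude
                * np.sin(2.0 * np.pi * 20.0 * tb)
                * np.hanning(bn)
            )
            emg[b0 : b0 + bn] += burst

    rec = SessionRecording(
        emg=emg,
        tacs_monitor=monitor,
        sampling_rate=fs,
        pulse_markers=tms["sample"].to_numpy(dtype=int),
        control_markers=events.loc[events["kind"] == "control", "sample"].to_numpy(
            dtype=int
        ),
        participant=cfg.participant,
        session=cfg.session,
        tacs_frequency=cfg.tacs_frequency,
    )
    truth = GroundTruth(
        preferred_phase=cfg.preferred_phase,
        modulation_depth=cfg.modulation_depth,
        baseline_mep=cfg.baseline_mep,
        pulses=events,
    )
    return rec, truth


def generate_cohort(
    n_participants: int,
    base_config: Optional[GenerationConfig] = None,
    *,
    seed: Optional[int] = None,
    alpha_frequency: float = 10.0,
    beta_frequency: float = 20.0,
    alpha_preferred_phase: float = 180.0,
    beta_preferred_phase: float = 0.0,
    baseline_spread_sigma: float = 0.35,
) -> tuple[pd.DataFrame, Iterator[tuple[SessionRecording, GroundTruth]]]:
    """Generate a multi-participant cohort: participant table + sessions.

    Each participant contributes one alpha-session (10 Hz) and one
    beta-session (20 Hz) in counterbalanced order (``session_order`` in
    the table alternates ``alpha-first``/``beta-first``).  Per-frequency
    preferred phases default to the trough for alpha and the peak for
    beta.  Participant baselines vary lognormally around the base
    config's ``baseline_mep``.

    Returns the participant table (id, age, sex, mt_s01, mt_s02,
    session_order) and a lazy iterator of ``(recording, ground_truth)``
    pairs in participant order, alpha before beta — sessions are
    rendered on demand so a full cohort never has to sit in memory.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if base_config is None:
        base_config = GenerationConfig(seed=0)
    if seed is None:
        seed = base_config.seed

    ss = np.random.SeedSequence(seed)
    table_rng = np.random.default_rng(ss.spawn(1)[0])
    session_seeds = [s.generate_state(1)[0] % (2**31) for s in ss.spawn(2 * n_participants)]

    ids = [f"SP{i + 1:02d}" for i in range(n_participants)]
    ages = np.clip(np.round(table_rng.normal(26.6, 5.7, n_participants)), 18, 45)
    sexes = np.where(table_rng.random(n_participants) < 2 / 3, "F", "M")
    mt1 = np.clip(np.round(table_rng.normal(69.0, 7.5, n_participants)), 40, 90)
    mt2 = np.clip(mt1 + table_rng.choice([0, 0, 0, -1, 1, 5], n_participants), 40, 90)
    baselines = base_config.baseline_mep * table_rng.lognormal(
        0.0, baseline_spread_sigma, n_participants
    )
    participants = pd.DataFrame(
        {
            "id": ids,
            "age": ages,
            "sex": sexes,
            "mt_s01": mt1,
            "mt_s02": mt2,
            "session_order": [
                "alpha-first" if i % 2 == 0 else "beta-first"
                for i in range(n_participants)
            ],
        }
    )

    def _sessions() -> Iterator[tuple[SessionRecording, GroundTruth]]:
        from dataclasses import replace

        for i, pid in enumerate(ids):
            for j, (freq, pref) in enumerate(
                ((alpha_frequency, alpha_preferred_phase), (beta_frequency, beta_preferred_phase))
            ):
                cfg = replace(
                    base_config,
                    seed=int(session_seeds[2 * i + j]),
                    tacs_frequency=freq,
                    preferred_phase=pref,
                    baseline_mep=float(baselines[i]),
                    participant=pid,
                    session="alpha" if freq == alpha_frequency else "beta",
                )
                yield generate_session(cfg)

    return participants, _sessions()
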