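"""Reading and writing the recording and table formats the pipeline touches.

Two on-disk dialects carry a session:

* the BrainVision triad (``.vhdr``/``.vmrk``/``.eeg``) as produced by
  Brain Vision Recorder — read through :mod:`mne`, written by a minimal
  Core-1.0 writer (multiplexed IEEE float32, markers as ``Stimulus``
  events);
* a plain-text fixture dialect (``#``-prefixed metadata header followed
  by tab-separated ``time_s  emg_uv  tacs_au`` rows, markers in a
  sibling ``*.markers.tsv`` file) for human-readable fixtures; see
  ``docs/formats.md``.

EMG is held in microvolts throughout: the pre-contraction rejection
threshold and the motor-threshold definition are both stated in uV.
Pulse markers are 0-based sample indices internally; the 1-based
BrainVision marker positions are converted at the boundary.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "SessionRecording",
    "read_brainvision",
    "write_brainvision",
    "read_fixture",
    "write_fixture",
    "read_participant_table",
    "load_example_cohort",
]

PARTICIPANT_COLUMNS = ("id", "age", "sex", "mt_s01", "mt_s02")

#: Marker descriptions used in BrainVision files.
TMS_MARKER = "S  1"
CONTROL_MARKER = "S  2"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input whose content violates an invariant."""


@dataclass
class SessionRecording:
    """One participant-session: EMG + tACS monitor channels with TMS markers.

    Attributes
    ----------
    emg : ndarray
        FDI surface EMG in microvolts.
    tacs_monitor : ndarray
        Monitored tACS oscillation (arbitrary units), same length as
        ``emg``.
    sampling_rate : float
        Samples per second (2000 in the recorded sessions).
    pulse_markers : ndarray of int
        0-based sample indices of TMS pulses, strictly increasing.
    control_markers : ndarray of int
        Sample indices of the no-pulse control condition; recorded but
        excluded from analysis.
    participant, session : str
        Labels; ``session`` is "alpha" (10 Hz) or "beta" (20 Hz).
    tacs_frequency : float
        Commanded tACS frequency in Hz.
    tacs_onset_sample : int
        Sample at which the commanded current starts at phase 0.
    hardware_bandpass_hz : tuple
        Amplifier band-pass, recorded as metadata only (filtering was
        done in hardware; no re-filtering is applied).
    """

    emg: np.ndarray
    tacs_monitor: np.ndarray
    sampling_rate: float
    pulse_markers: np.ndarray
    participant: str = "SYN01"
    session: str = "alpha"
    tacs_frequency: float = 10.0
    control_markers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    tacs_onset_sample: int = 0
    hardware_bandpass_hz: tuple = (10.0, 2000.0)

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.tacs_monitor = np.asarray(self.tacs_monitor, dtype=float)
        self.pulse_markers = np.asarray(self.pulse_markers, dtype=int)
        self.control_markers = np.asarray(self.control_markers, dtype=int)
        if self.emg.shape != self.tacs_monitor.shape or self.emg.ndim != 1:
            raise ValidationError("EMG and tACS monitor must be 1-D and equal length")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        for name, m in (("pulse", self.pulse_markers), ("control", self.control_markers)):
            if m.size and (np.any(np.diff(m) <= 0)):
                raise ValidationError(f"{name} markers must be strictly increasing")
            if m.size and (m[0] < 0 or m[-1] >= self.emg.size):
                raise ValidationError(f"{name} marker beyond signal bounds")

    @property
    def n_samples(self) -> int:
        return self.emg.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "SessionRecording":
        return replace(
            self,
            emg=self.emg.copy(),
            tacs_monitor=self.tacs_monitor.copy(),
            pulse_markers=self.pulse_markers.copy(),
            control_markers=self.control_markers.copy(),
        )


# ---------------------------------------------------------------------------
# BrainVision triad
# ---------------------------------------------------------------------------

_VHDR_TEMPLATE = """\
BrainVision Data Exchange Header File Version 1.0
; Written by tacsmep

[Common Infos]
Codepage=UTF-8
DataFile={data_file}
MarkerFile={marker_file}
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels=2
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Each entry: Ch<number>=<Name>,<Reference>,<Resolution "1">,<Unit>
Ch1={emg_name},,1,µV
Ch2={tacs_name},,1,µV

[Comment]
participant={participant}
session={session}
tacs_frequency_hz={tacs_frequency}
tacs_onset_sample={tacs_onset_sample}
hardware_bandpass_hz={bp_lo},{bp_hi}
"""


def write_brainvision(
    rec: SessionRecording,
    header_path,
    *,
    emg_channel: str = "EMG",
    tacs_channel: str = "TACS",
) -> Path:
    """Write a session as a BrainVision Core 1.0 triad.

    Data are multiplexed IEEE float32 with resolution 1 uV; TMS pulses
    become ``Stimulus,S  1`` markers and no-pulse controls
    ``Stimulus,S  2`` (positions 1-based per the format).  Session
    metadata is carried in the header's ``[Comment]`` section.
    """
    header_path = Path(header_path)
    if header_path.suffix != ".vhdr":
        raise ValueError("header_path must end in .vhdr")
    base = header_path.with_suffix("")
    eeg_path = base.with_suffix(".eeg")
    vmrk_path = base.with_suffix(".vmrk")

    header_path.write_text(
        _VHDR_TEMPLATE.format(
            data_file=eeg_path.name,
            marker_file=vmrk_path.name,
            sampling_interval=int(round(1e6 / rec.sampling_rate)),
            emg_name=emg_channel,
            tacs_name=tacs_channel,
            participant=rec.participant,
            session=rec.session,
            tacs_frequency=rec.tacs_frequency,
            tacs_onset_sample=rec.tacs_onset_sample,
            bp_lo=rec.hardware_bandpass_hz[0],
            bp_hi=rec.hardware_bandpass_hz[1],
        ),
        encoding="utf-8",
    )

    lines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        "",
        "[Marker Infos]",
        "; Each entry: Mk<number>=<Type>,<Description>,<Position>,<Size>,<Channel>",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    events = [(int(s), TMS_MARKER) for s in rec.pulse_markers] + [
        (int(s), CONTROL_MARKER) for s in rec.control_markers
    ]
    for k, (sample, desc) in enumerate(sorted(events), start=2):
        lines.append(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0")
    vmrk_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    data = np.column_stack([rec.emg, rec.tacs_monitor]).astype("<f4")
    data.tofile(eeg_path)
    return header_path


def _parse_vhdr_comment(header_path: Path) -> dict:
    meta = {}
    in_comment = False
    for line in header_path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = line.strip()
        if line.startswith("["):
            in_comment = line.lower() == "[comment]"
            continue
        if in_comment and "=" in line and not line.startswith(";"):
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_brainvision(
    header_path,
    *,
    emg_channel: str = "EMG",
    tacs_channel: str = "TACS",
) -> SessionRecording:
    """Read a BrainVision triad into a :class:`SessionRecording`.

    Channels are mapped by name (the recorder's channel labels are
    site-specific, so the mapping is an argument); EMG is converted to
    microvolts.  ``Stimulus`` markers of the TMS type become 0-based
    pulse sample indices.
    """
    import mne

    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header file not found: {header_path}")
    try:
        raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    except FileNotFoundError as exc:
        raise FormatError(f"inconsistent BrainVision triad: {exc}") from exc
    except Exception as exc:  # malformed header / data
        raise FormatError(f"cannot read BrainVision triad {header_path}: {exc}") from exc

    missing = [name for name in (emg_channel, tacs_channel) if name not in raw.ch_names]
    if missing:
        raise ValidationError(
            f"channel(s) {missing} not in recording; available: {raw.ch_names}"
        )
    # mne scales uV channels to volts internally; undo for uV-native storage.
    emg = raw.get_data(picks=[emg_channel])[0] * 1e6
    tacs = raw.get_data(picks=[tacs_channel])[0] * 1e6

    fs = float(raw.info["sfreq"])
    pulses, controls = [], []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        sample = int(round(onset * fs))
        if desc.endswith(TMS_MARKER):
            pulses.append(sample)
        elif desc.endswith(CONTROL_MARKER):
            controls.append(sample)

    meta = _parse_vhdr_comment(header_path)
    bp = meta.get("hardware_bandpass_hz", "10.0,2000.0").split(",")
    return SessionRecording(
        emg=emg,
        tacs_monitor=tacs,
        sampling_rate=fs,
        pulse_markers=np.asarray(sorted(pulses), dtype=int),
        control_markers=np.asarray(sorted(controls), dtype=int),
        participant=meta.get("participant", header_path.stem),
        session=meta.get("session", "unknown"),
        tacs_frequency=float(meta.get("tacs_frequency_hz", 10.0)),
        tacs_onset_sample=int(meta.get("tacs_onset_sample", 0)),
        hardware_bandpass_hz=(float(bp[0]), float(bp[1])),
    )


# ---------------------------------------------------------------------------
# Plain-text fixture dialect
# ---------------------------------------------------------------------------

def _markers_path(path: Path) -> Path:
    return path.with_name(path.stem + ".markers.tsv")


def write_fixture(rec: SessionRecording, path) -> Path:
    """Write a session in the plain-text fixture dialect.

    Samples are written to six decimal places, so the round-trip is
    lossless to 1e-6 uV.
    """
    path = Path(path)
    buf = _io.StringIO()
    buf.write("# tacsmep-fixture v1\n")
    buf.write(f"# participant: {rec.participant}\n")
    buf.write(f"# session: {rec.session}\n")
    buf.write(f"# tacs_frequency_hz: {rec.tacs_frequency}\n")
    buf.write(f"# sampling_rate_hz: {rec.sampling_rate}\n")
    buf.write(f"# tacs_onset_sample: {rec.tacs_onset_sample}\n")
    buf.write(
        f"# hardware_bandpass_hz: {rec.hardware_bandpass_hz[0]},{rec.hardware_bandpass_hz[1]}\n"
    )
    buf.write(f"# n_samples: {rec.n_samples}\n")
    buf.write("time_s\temg_uv\ttacs_au\n")
    t = np.arange(rec.n_samples) / rec.sampling_rate
    for ti, e, m in zip(t, rec.emg, rec.tacs_monitor):
        buf.write(f"{ti:.6f}\t{e:.6f}\t{m:.6f}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")

    mlines = ["sample\tkind"]
    events = [(int(s), "pulse") for s in rec.pulse_markers] + [
        (int(s), "control") for s in rec.control_markers
    ]
    for sample, kind in sorted(events):
        mlines.append(f"{sample}\t{kind}")
    _markers_path(path).write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return path


def read_fixture(path) -> SessionRecording:
    """Read a session written by :func:`write_fixture`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"fixture file not found: {path}")
    meta: dict = {}
    header_rows = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    required = {"participant", "session", "tacs_frequency_hz", "sampling_rate_hz"}
    if not required <= meta.keys():
        raise FormatError(
            f"fixture header missing keys: {sorted(required - meta.keys())}"
        )
    try:
        table = pd.read_csv(path, sep="\t", skiprows=header_rows)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("fixture has no data section") from exc
    if table.empty:
        raise FormatError("fixture has an empty data section")
    for col in ("time_s", "emg_uv", "tacs_au"):
        if col not in table.columns:
            raise FormatError(f"fixture data section lacks column {col!r}")
        if table[col].isna().any():
            raise FormatError("ragged or non-numeric rows in fixture data section")

    mpath = _markers_path(path)
    if not mpath.exists():
        raise FormatError(f"marker sidecar not found: {mpath}")
    markers = pd.read_csv(mpath, sep="\t")
    pulses = markers.loc[markers["kind"] == "pulse", "sample"].to_numpy(dtype=int)
    controls = markers.loc[markers["kind"] == "control", "sample"].to_numpy(dtype=int)
    n = len(table)
    for arr in (pulses, controls):
        if arr.size and (arr.min() < 0 or arr.max() >= n):
            raise ValidationError("marker beyond final sample of fixture")

    bp = meta.get("hardware_bandpass_hz", "10.0,2000.0").split(",")
    return SessionRecording(
        emg=table["emg_uv"].to_numpy(dtype=float),
        tacs_monitor=table["tacs_au"].to_numpy(dtype=float),
        sampling_rate=float(meta["sampling_rate_hz"]),
        pulse_markers=np.sort(pulses),
        control_markers=np.sort(controls),
        participant=meta["participant"],
        session=meta["session"],
        tacs_frequency=float(meta["tacs_frequency_hz"]),
        tacs_onset_sample=int(meta.get("tacs_onset_sample", 0)),
        hardware_bandpass_hz=(float(bp[0]), float(bp[1])),
    )


# ---------------------------------------------------------------------------
# Participant tables
# ---------------------------------------------------------------------------

def read_participant_table(path) -> pd.DataFrame:
    """Read a delimited participant table (id, age, sex, MT% per session).

    Accepts tab- or comma-separated text with a header row.  Each row is
    validated: age must be a positive number, motor thresholds must lie
    in (0, 100] %MSO, sex must be F or M.  An empty file yields an empty
    table with the schema in place.
    """
    path = Path(path)
    if not path.read_text(encoding="utf-8").strip():
        return pd.DataFrame(columns=list(PARTICIPANT_COLUMNS))
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(PARTICIPANT_COLUMNS))
    table.columns = [str(c).strip().lower() for c in table.columns]
    missing = [c for c in PARTICIPANT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"participant table missing columns: {missing}")
    table = table[list(PARTICIPANT_COLUMNS)].copy()

    for row in table.itertuples():
        label = f"participant row {row.Index} (id={row.id!r})"
        for col in ("age", "mt_s01", "mt_s02"):
            value = getattr(row, col)
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ValidationError(f"{label}: non-numeric {col} {value!r}") from None
            if col == "age" and value <= 0:
                raise ValidationError(f"{label}: age must be positive")
            if col.startswith("mt") and not (0 < value <= 100):
                raise ValidationError(f"{label}: MT must lie in (0, 100] %MSO")
        if str(row.sex).strip().upper() not in {"F", "M"}:
            raise ValidationError(f"{label}: sex must be F or M")

    table["age"] = table["age"].astype(float)
    table["mt_s01"] = table["mt_s01"].astype(float)
    table["mt_s02"] = table["mt_s02"].astype(float)
    table["sex"] = table["sex"].astype(str).str.strip().str.upper()
    table["id"] = table["id"].astype(str)
    return table


def load_example_cohort() -> pd.DataFrame:
    """Demographics and motor thresholds of the 15-participant example cohort.

    Ships with the package as a small TSV (id, age, sex, MT %MSO for the
    two counterbalanced sessions); used by the worked examples and by
    the reproduction script.
    """
    from importlib.resources import files

    return read_participant_table(files("tacsmep.data") / "example_cohort.tsv")
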