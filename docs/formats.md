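# On-disk formats

## BrainVision triad (`.vhdr` / `.vmrk` / `.eeg`)

Sessions are read from and written to BrainVision Core 1.0:

* `.vhdr` — INI-style text header.  The writer emits two channels
  (`Ch1=EMG`, `Ch2=TACS` by default; names are configurable on both read and
  write since recorder channel labels are site-specific), binary multiplexed
  IEEE float32 data with resolution 1 µV, and a `SamplingInterval` in µs
  (500 at 2 kHz).  Session metadata (participant, session label, tACS
  frequency, tACS onset sample, hardware band-pass) is carried as
  `key=value` lines in the `[Comment]` section, which BrainVision readers
  ignore.
* `.vmrk` — markers.  TMS pulses are `Stimulus,S  1`, no-pulse control
  events `Stimulus,S  2`, positions 1-based per the format; they are
  converted to 0-based sample indices at the boundary.
* `.eeg` — little-endian float32, multiplexed (sample-major).

Reading goes through `mne.io.read_raw_brainvision`; since the writer is
independent of mne, the round-trip test cross-checks both.  EMG values are
converted back to µV (mne holds data in volts internally).  Round-trip error
is bounded by float32 resolution (< 10⁻³ µV at MEP scale).

## Plain-text fixture dialect (`*.tsv` + `*.markers.tsv`)

A human-readable dialect for small fixtures and debugging:

```
# tacsmep-fixture v1
# participant: SYN01
# session: alpha
# tacs_frequency_hz: 10.0
# sampling_rate_hz: 2000.0
# tacs_onset_sample: 0
# hardware_bandpass_hz: 10.0,2000.0
# n_samples: 600000
time_s	emg_uv	tacs_au
0.000000	-3.412199	1.012706
0.000500	2.150844	0.986001
...
```

Samples are written to six decimal places (lossless round-trip to 1e-6 µV).
Markers live in a sibling file named by replacing `.tsv` with
`.markers.tsv`:

```
sample	kind
4116	pulse
12060	control
```

`kind` is `pulse` (TMS) or `control` (no-pulse).  Readers validate: required
header keys present, complete numeric rows, markers within the signal
bounds; violations raise `FormatError` / `ValidationError` rather than
truncating silently.

## Tabular artifacts

All tables are tab-separated text with a header row:

* **participant table** — `id, age, sex, mt_s01, mt_s02` (motor thresholds
  in %MSO per session); comma-separated input is also accepted.
* **ground-truth sidecar** (`*.truth.tsv`) — `#`-prefixed header lines with
  the hidden model parameters (preferred phase, modulation depth, baseline),
  then one row per scheduled event: sample, time, block, kind, target and
  true phase, model and rendered amplitude, pre-contraction flag.
* **trial table** — one row per TMS pulse: pulse index, time, estimated
  phase, fit r², bin, MEP amplitude, rejected flag and reason
  (`none | precontraction | unphased | window`).
* **bin summaries** — participant × session × bin: trial count, median MEP,
  z-scored median, CV, degenerate flag.
* **group tables** — per-bin group stats and the pairwise contrast table
  (measure, bin pair, n, mean difference, d, t, p, Holm-adjusted p).
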