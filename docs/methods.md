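# Methods

## The problem

tACS applies a weak sinusoidal current between scalp electrodes (here the
montage of interest is M1–Pz) and is assumed to entrain cortical activity at
the commanded frequency.  Single suprathreshold TMS pulses over M1, timed to
land at chosen phases of the tACS cycle, probe whether corticospinal
excitability — indexed by the peak-to-peak MEP amplitude in the FDI muscle —
and its trial-to-trial variability depend on stimulation phase.  `tacsmep`
implements the offline analysis of such sessions, replacing the
visual-inspection steps of typical lab practice (sinusoid-shape checks,
phase reading, trial screening) with automatic, tested equivalents.

## Phase estimation

The tACS frequency f is commanded and known exactly, so phase is estimated
parametrically rather than with a Hilbert transform: a least-squares fit of
`A·cos(2πft + φ) + c` (linear in `A cos φ, −A sin φ, c`, solved in closed
form) over a window of **3 full cycles ending 5 ms before the pulse**,
extrapolated to the pulse sample.  A Hilbert phase would need artifact-free
signal on both sides of the pulse; the parametric fit needs only the
pre-pulse window and degrades gracefully with monitor noise (median circular
error ≈ 0.3° at 20 dB SNR, ≈ 3° at 0 dB; the test suite bounds these at 2°
and 10°).

Conventions and thresholds:

* **Phase convention** — 0° is the positive peak of the commanded current,
  increasing with time: 90° falling edge, 180° trough, 270° rising edge.
* **Bins** — half-open quadrants at ±45° around each nominal phase
  (peak [315°, 45°), falling [45°, 135°), trough [135°, 225°),
  rising [225°, 315°)).  Lab practice classifies by eye and states no
  boundaries; symmetric quadrants are the natural choice.
* **Polarity** — if the recording montage inverts the monitored waveform
  (anode/cathode swap), the fitted phase at tACS onset sits near 180°
  instead of 0°; the flag is set and all phases shifted by 180°.
  "Phase-reversal" could alternatively mean a 90° sine/cosine convention
  shift; the shift amount is a config parameter (`reversal_shift_deg`,
  default 180) so the interpretation is swappable, and a montage-known
  override (`force_reversed`) bypasses detection entirely — polarity is a
  setup fact and should not be guessed when known.
* **Unphased trials** — fit r² < 0.8 (or no available window) excludes a
  trial.  The threshold sits far above the noise-only fit distribution
  (median r² < 0.05 over white-noise draws) and far below clean-signal fits
  (r² > 0.95 at 20 dB); 0.5 plays the same role for the polarity check,
  below which polarity is declared ambiguous and left uncorrected with a
  warning.

## Trial rejection and MEP quantification

A trial is rejected when the EMG peak-to-peak excursion in the **500 ms
window preceding the pulse** exceeds **50 µV** (muscle pre-contraction or
noise).  The window is anchored at the pulse rather than at MEP onset — the
two differ by the ~20 ms MEP latency, immaterial for a quiescence check,
and the pulse sample is unambiguous.  "Exceeds 50 µV" is read as
peak-to-peak excursion; a maximum-absolute-value variant is available via
config.  Rejection is causal: it never inspects post-pulse samples.

MEP amplitude is the peak-to-peak EMG in a **15–55 ms post-pulse window**
(spanning FDI MEP latencies, clear of the stimulation artifact; the first
5 ms are additionally blanked).  Trials whose windows fall outside the
recording are dropped with reason `window`.

## Summaries and group statistics

Per participant × session × bin over accepted trials:

* **median MEP amplitude** (µV);
* **z-scored median** — z-score across the participant's four bin medians
  (mean 0, sample-SD 1).  This scope forces each participant's z-profile to
  sum to zero, hence group means per bin also sum to ≈ 0 — the pattern such
  studies report.  Z-scoring across trials would not have this property.
  Participants with an empty or zero-variance bin have undefined z-profiles
  and are excluded from group z-analyses (flagged `degenerate`).
* **CV** — sample SD / mean of the raw (not z-scored) accepted amplitudes;
  ≥ 2 trials required.  CV is invariant under amplitude rescaling.

Group level, per frequency: mean ± SD (and SEM = SD/√n) of z-median and CV
per bin; all six pairwise bin contrasts per measure as paired two-tailed
t-tests with the paired standardized mean difference
**d_z = mean(a−b) / SD(a−b)** — the within-subject Cohen's d, for which 0.5
is conventionally "medium".  A pooled-SD d is available as an option.
P-values are uncorrected, matching field practice for this design; a
Holm-adjusted column is emitted alongside as a clearly labelled extension.
The efficacy-versus-variability report places each bin at (mean z-median,
mean CV) with SEM bars and flags Pareto-optimal bins (no other bin both
more excitable and less variable).

The headline diagnostic fits the cosine excitability model
`amplitude = b·(1 + m·cos(θ − φ₀))` to accepted trials by exact least
squares (linear reparameterisation `b + c₁cos θ + c₂sin θ`;
`m = |(c₁,c₂)|/b`, `φ₀ = atan2(c₂,c₁)`).  With multiplicative amplitude
noise the baseline estimate absorbs the noise mean (×e^{σ²/2}); φ₀ and the
relative depth are unaffected.  For cohorts, amplitudes are normalised per
participant (divided by the participant's mean accepted amplitude) before
pooling, so baseline spread does not dilute the fit.  At default noise a
single ~120-trial session recovers φ₀ with SE ≈ 15°, so per-session
recovery within ±20° holds only in median across replicates; a pooled
15-participant cohort has SE ≈ 4° and recovers within ±20° essentially
always.

## The synthetic generator

`generate_session` renders sessions from a known ground truth so every
stage has an oracle.  Defaults mirror the experimental design being
analysed: 2 kHz sampling, 4 blocks × 5 min, pulses at 4 ± 1 s intervals
randomly assigned TMS/no-pulse (p = 0.5, the no-pulse condition is rendered
as markers only and excluded from analysis), four phase targets in
randomised balanced order.  Model and noise parameters, with rationale:

| parameter | default | why |
|---|---|---|
| `phase_targeting_jitter_sd` | 10° | targeting precision is not published for this paradigm; Gaussian in phase (not time) gives direct control of bin leakage (4.5 SD to a boundary ⇒ negligible) |
| `baseline_mep` | 1000 µV | typical suprathreshold FDI MEP |
| `modulation_depth` | 0.3 | produces group z-profiles of the magnitude such studies report |
| `preferred_phase` | 180° (alpha) / 0° (beta in cohorts) | trough- vs peak-preferring configurations |
| `trial_noise` (lognormal σ) | 0.5 | yields CV ≈ 0.53, inside the 0.49–0.61 band typical of phase-binned MEP data |
| `emg_noise_sd` | 5 µV | a relaxed-EMG baseline; its expected 500 ms peak-to-peak (~32 µV) stays below the 50 µV criterion, as real accepted baselines must (10 µV noise would have ~65 µV excursions and reject everything) |
| `precontraction_rate` | 0.05 | occasional failed relaxation |
| `precontraction_amplitude` | 100 µV p-p | clearly supra-threshold 20 Hz burst, 300 ms, inside the pre-window |
| artifact | 2 ms saturated square, 5 mV | only its exclusion matters |
| MEP waveform | biphasic half-sines 7 + 8 ms at 22 ms latency, 0.6/0.4 split | physiologically conventional; only peak-to-peak matters downstream |
| `monitor_noise_sd` | 0.0707 a.u. | ≈ 20 dB SNR at unit monitor amplitude |

Pulse times are snapped to the commanded sinusoid so the *true* phase is
exact at the quantised sample (1.8°/sample at 10 Hz, 2 kHz); the mean
noiseless amplitude over the four exact targets equals the baseline
(cosine quadrature sums to zero).  The ground-truth ledger records both the
model amplitude and the rendered (post-lognormal) amplitude: extraction
accuracy is judged against the rendered value, which is what the EMG
actually contains.

**What the generator does not emulate:** physiological background EMG
(coloured, bursty) rather than Gaussian noise; MEP latency/shape
variability; drifts in tACS amplitude or electrode impedance; true neural
entrainment dynamics (the phase→amplitude transfer is phenomenological by
design); real recording artifacts (movement, line noise).  Passing tests
therefore demonstrate the *analysis* is correct and calibrated under the
stated model, not that the biological effect exists or that real data are
this clean.

## Monte-Carlo experiments and problem sizes

Statistical properties (recovery rates, type-I calibration) are measured on
the generator's **trial-level sampling layer** — the same phase-jitter /
cosine / lognormal / rejection model the renderer consumes, summarised with
the same median/CV/z and paired-t kernels — skipping only waveform
rendering and window extraction, which the end-to-end tests validate
separately on rendered full-length cohorts.  Sizes used: 100 replicate
15-participant cohorts (~150 scheduled trials/session) per configuration
for recovery; 1000 replicates for null calibration; a rendered
4-participant full-length cohort for end-to-end recovery.  These sizes give
binomial error ≤ ~2% on rates and keep the whole suite in seconds.

Under the null (depth 0) each of the twelve pairwise contrasts is
significant at α = 0.05 in 3–7% of replicates; the paired t-test is
approximately exact here because within-participant bin summaries are
exchangeable under the null, making difference scores symmetric about zero.

## Numerical and degenerate-input choices

* Sinusoid fits require ≥ 2 full cycles and non-zero variance; amplitude is
  returned ≥ 0 with φ in [0, 360).
* Bin boundaries are half-open `[lo, hi)`; classification is total on the
  real line (angles wrapped), so θ and θ + 360k agree.
* `a = b` in a paired contrast yields d = 0, t = 0, p = 1 with a degenerate
  flag; a non-zero constant difference has undefined d (NaN), flagged.
* Zero-marker recordings analyse to an empty trial table; group analysis
  refuses cohorts with fewer than two complete participants.
* Sample SDs (n−1) throughout; single-participant cohort SDs are NaN.
* All generation is seeded (`seed` is mandatory in the config); identical
  seeds give bit-identical sessions.

## Known limitations

* Offline only — no real-time phase prediction or triggering.
* No circular statistics (Rayleigh, circular–linear correlation); the
  cosine fit is the only circular element, matching the bin-wise linear
  analysis this pipeline mirrors.
* No MEP latency or silent-period analysis; amplitude only.
* BrainVision support covers the Core 1.0 multiplexed float32 layout the
  writer produces plus whatever `mne` reads; EDF/GDF are out of scope.
* The motor-threshold procedure (200–500 µV criterion MEPs in ~5/10
  trials) enters only as participant-table fields; it is not simulated.
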