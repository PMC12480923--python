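# tacsmep

Offline analysis of **tACS-phase-aligned TMS** experiments on corticospinal
excitability.

When single TMS pulses over primary motor cortex are delivered in phase with a
transcranial alternating current stimulation (tACS) oscillation, the evoked
motor potential (MEP) in a hand muscle depends on *where in the tACS cycle* the
pulse lands.  `tacsmep` turns dual-channel recordings (FDI surface EMG plus a
monitored tACS oscillation, 2 kHz, TMS event markers) into per-phase
excitability and variability statistics:

1. **Phase estimation** — the tACS frequency is commanded and known, so the
   instantaneous phase at each pulse is obtained from a least-squares sinusoid
   fit `A·cos(2πft + φ) + c` over the 3 cycles ending 5 ms before the pulse,
   extrapolated to the pulse sample.  Monitor-polarity inversion (swapped
   anode/cathode) is detected and corrected by a 180° shift.
2. **Phase binning** — quadrants centred on the peak (0°), falling edge (90°),
   trough (180°) and rising edge (270°) of the cycle, boundaries at ±45°.
3. **Trial rejection** — trials with pre-contraction or noise exceeding
   50 µV peak-to-peak in the 500 ms pre-pulse window are excluded, as are
   trials whose sinusoid fit is unavailable or poor (r² < 0.8).
4. **MEP quantification** — peak-to-peak EMG amplitude in a 15–55 ms
   post-pulse window (stimulation artifact blanked).
5. **Statistics** — per participant and phase bin: median amplitude, its
   z-score across the four bin medians (mean 0, SD 1 within participant) and
   the coefficient of variation CV = SD/mean of raw amplitudes.  Group level:
   per-bin means ± SD, all six pairwise paired contrasts per measure with
   paired Cohen's d (d_z = mean Δ / SD Δ) and two-tailed t-tests, and an
   efficacy-versus-variability frontier report.

A first-class **synthetic-data generator** renders complete sessions from a
known ground-truth model — `amplitude = b·(1 + m·cos(θ − φ₀))` with lognormal
trial noise, stimulation artifacts, biphasic MEP waveforms and pre-contraction
bursts — so every stage of the pipeline is testable without any recordings.
Sessions round-trip through the BrainVision triad (`.vhdr/.vmrk/.eeg`) and a
plain-text fixture dialect (see `docs/formats.md`).

## Worked example

```python
from tacsmep import (GenerationConfig, generate_session, analyze_session,
                     summarize_bins, fit_phase_modulation)

cfg = GenerationConfig(seed=1)          # 10 Hz, trough-preferring, depth 0.3
rec, truth = generate_session(cfg)      # 20 min session, ~150 TMS pulses
trials = analyze_session(rec)
summary = summarize_bins(trials)
print(summary[["bin", "n_trials", "median_mep", "z_median", "cv"]]
      .round(3).to_string(index=False))

acc = trials[~trials["rejected"]]
fit = fit_phase_modulation(acc["phase_deg"].to_numpy(),
                           acc["mep_amplitude"].to_numpy())
print(f"recovered preferred phase: {fit.preferred_phase_deg:.1f} deg "
      f"(truth {truth.preferred_phase:.0f}), depth {fit.depth:.2f} "
      f"(truth {truth.modulation_depth})")
```

prints

```
    bin  n_trials  median_mep  z_median    cv
   peak        32     649.849    -1.268 0.638
falling        33    1175.183     0.452 0.422
 trough        41    1361.106     1.061 0.466
 rising        31     962.053    -0.246 0.496
recovered preferred phase: 164.1 deg (truth 180), depth 0.29 (truth 0.3)
```

The session was generated with its preferred phase at the trough, and the
analysis recovers exactly that: the trough bin has the largest median MEP
(1361 µV, z = +1.06), the peak the smallest (650 µV, z = −1.27), and the
pooled cosine fit lands 16° from the programmed phase with the modulation
depth recovered to 0.01.  CVs near 0.5 reflect the lognormal(σ = 0.5)
trial-to-trial noise.

The same steps are available from the shell:

```sh
tacsmep generate --config gen.yaml --out data/ --cohort 15
tacsmep analyze data/*.vhdr --out results/
tacsmep summarize results/bin_summaries.tsv --out results/ \
        --participants data/participants.tsv
tacsmep report results/bin_summaries.tsv --out results/
```

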