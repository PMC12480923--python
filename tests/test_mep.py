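"""Pre-contraction rejection, amplitude extraction, bin summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tacsmep.mep import (
    InsufficientWindowError,
    count_pulses_per_bin,
    mep_amplitude,
    reject_precontraction,
    summarize_bins,
)

FS = 2000.0
PULSE = 3000  # 1.5 s in


def _emg_with_burst(burst_ptp=None, burst_end_before_pulse_ms=100.0, n=8000):
    """Flat EMG with an optional sinusoidal burst of given peak-to-peak."""
    emg = np.zeros(n)
    if burst_ptp is not None:
        bn = int(0.2 * FS)
        end = PULSE - int(burst_end_before_pulse_ms * FS / 1000.0)
        t = np.arange(bn) / FS
        emg[end - bn : end] = 0.5 * burst_ptp * np.sin(2 * np.pi * 20.0 * t)
    return emg


class TestRejectPrecontraction:
    def test_60uv_burst_in_window_rejected(self):
        assert reject_precontraction(_emg_with_burst(60.0), PULSE, FS) is True

    def test_40uv_burst_kept(self):
        assert reject_precontraction(_emg_with_burst(40.0), PULSE, FS) is False

    def test_burst_ending_600ms_before_pulse_kept(self):
        emg = _emg_with_burst(60.0, burst_end_before_pulse_ms=600.0)
        assert reject_precontraction(emg, PULSE, FS) is False

    def test_insufficient_window_raises(self):
        with pytest.raises(InsufficientWindowError):
            reject_precontraction(np.zeros(8000), 500, FS)

    def test_absolute_value_variant(self):
        emg = np.zeros(8000)
        emg[PULSE - 400] = 45.0  # one-sided: ptp 45, max abs 45
        assert reject_precontraction(emg, PULSE, FS, measure="ptp") is False
        emg[PULSE - 399] = -10.0  # ptp now 55
        assert reject_precontraction(emg, PULSE, FS, measure="ptp") is True
        assert reject_precontraction(emg, PULSE, FS, measure="abs") is False

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_rejection_is_causal(self, seed):
        """Altering post-pulse samples never changes the rejection call."""
        rng = np.random.default_rng(seed)
        emg = rng.normal(0, 20, 8000)
        before = reject_precontraction(emg, PULSE, FS)
        emg[PULSE:] = rng.normal(0, 500, emg.size - PULSE)
        assert reject_precontraction(emg, PULSE, FS) == before


class TestMepAmplitude:
    def test_programmed_amplitude_recovered(self, clean_session):
        rec, truth = clean_session
        for row in truth.tms_pulses.head(10).itertuples():
            amp = mep_amplitude(rec.emg, int(row.sample), rec.sampling_rate)
            assert amp == pytest.approx(row.mep_rendered_uv, abs=1.0)

    def test_zero_signal_gives_zero(self):
        assert mep_amplitude(np.zeros(8000), PULSE, FS) == 0.0

    def test_window_past_end_raises(self):
        with pytest.raises(InsufficientWindowError):
            mep_amplitude(np.zeros(PULSE + 50), PULSE, FS)

    def test_extraction_tracks_rendered_amplitude_in_noise(self):
        """Cohort-level check: extracted vs rendered peak-to-peak
        amplitudes correlate > 0.95 at 10 uV baseline EMG noise."""
        from tacsmep.synthetic import GenerationConfig, generate_session

        cfg = GenerationConfig(
            seed=31, n_blocks=2, block_duration=120.0, emg_noise_sd=10.0, p_tms=1.0
        )
        rec, truth = generate_session(cfg)
        tms = truth.tms_pulses
        extracted = np.array(
            [mep_amplitude(rec.emg, int(s), rec.sampling_rate) for s in tms["sample"]]
        )
        r = np.corrcoef(extracted, tms["mep_rendered_uv"])[0, 1]
        assert r > 0.95


def _trials(amplitudes_by_bin, participant="P1", rejected_extra=()):
    rows = []
    i = 0
    for label, amps in amplitudes_by_bin.items():
        for a in amps:
            rows.append(
                {
                    "participant": participant,
                    "session": "alpha",
                    "tacs_frequency": 10.0,
                    "pulse_index": i * 1000 + 4000,
                    "time_s": 0.0,
                    "phase_deg": 0.0,
                    "fit_r2": 1.0,
                    "bin": label,
                    "mep_amplitude": a,
                    "rejected": False,
                    "rejection_reason": "none",
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    for idx in rejected_extra:
        df.loc[idx, ["rejected", "rejection_reason"]] = [True, "precontraction"]
    return df


class TestSummarizeBins:
    def test_hand_computed_z_scores(self):
        """Bin medians (700, 950, 1300, 1050) -> z-scores summing to 0
        with unit sample SD and signs (-, -, +, +)."""
        trials = _trials(
            {"peak": [700.0], "falling": [950.0], "trough": [1300.0], "rising": [1050.0]}
        )
        out = summarize_bins(trials).set_index("bin")
        medians = np.array([700.0, 950.0, 1300.0, 1050.0])
        expected = (medians - medians.mean()) / medians.std(ddof=1)
        got = out.loc[["peak", "falling", "trough", "rising"], "z_median"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got.sum() == pytest.approx(0.0, abs=1e-12)
        assert got.std(ddof=1) == pytest.approx(1.0)
        assert np.all(np.sign(got) == [-1, -1, 1, 1])

    def test_scale_invariance(self, rng):
        amps = {l: list(rng.lognormal(7, 0.5, 12)) for l in ("peak", "falling", "trough", "rising")}
        base = summarize_bins(_trials(amps)).set_index("bin")
        doubled = summarize_bins(
            _trials({l: [2 * a for a in v] for l, v in amps.items()})
        ).set_index("bin")
        np.testing.assert_allclose(doubled["cv"], base["cv"], rtol=1e-12)
        np.testing.assert_allclose(doubled["median_mep"], 2 * base["median_mep"], rtol=1e-12)
        np.testing.assert_allclose(doubled["z_median"], base["z_median"], atol=1e-9)

    def test_equal_medians_flagged_degenerate(self):
        trials = _trials({l: [500.0, 500.0] for l in ("peak", "falling", "trough", "rising")})
        out = summarize_bins(trials)
        assert out["degenerate"].all()
        assert out["z_median"].isna().all()

    def test_empty_bin_gives_zero_count_and_nan_stats(self):
        trials = _trials({"peak": [700.0, 800.0], "falling": [900.0], "trough": [1000.0]})
        out = summarize_bins(trials).set_index("bin")
        assert out.loc["rising", "n_trials"] == 0
        assert np.isnan(out.loc["rising", "median_mep"])
        assert out["degenerate"].all()  # z undefined with an empty bin
        assert np.isnan(out.loc["falling", "cv"])  # single trial: no CV

    def test_cv_uses_raw_amplitudes_with_sample_sd(self, rng):
        amps = list(rng.lognormal(7, 0.5, 30))
        trials = _trials({"peak": amps, "falling": amps, "trough": amps, "rising": amps})
        out = summarize_bins(trials).set_index("bin")
        expected = np.std(amps, ddof=1) / np.mean(amps)
        assert out.loc["peak", "cv"] == pytest.approx(expected, rel=1e-12)


class TestCountPulses:
    def test_uniform_counts(self, rng):
        amps = {l: list(rng.lognormal(7, 0.5, 30)) for l in ("peak", "falling", "trough", "rising")}
        counts = count_pulses_per_bin(_trials(amps))
        row = counts[counts["participant"] == "P1"].iloc[0]
        assert all(row[l] == 30 for l in ("peak", "falling", "trough", "rising"))
        mean_row = counts[counts["participant"] == "group-mean"].iloc[0]
        assert all(mean_row[l] == 30 for l in ("peak", "falling", "trough", "rising"))

    def test_all_rejected_gives_zeros(self, rng):
        trials = _trials({"peak": [1.0, 2.0], "trough": [3.0]}, rejected_extra=range(3))
        counts = count_pulses_per_bin(trials)
        row = counts[counts["participant"] == "P1"].iloc[0]
        assert all(row[l] == 0 for l in ("peak", "falling", "trough", "rising"))

    def test_accepted_fraction_matches_binomial_expectation(self):
        """Over many seeded sessions the accepted fraction of scheduled
        TMS trials tracks 1 - precontraction_rate."""
        from tacsmep.synthetic import GenerationConfig, sample_trial_outcomes, schedule_events

        rates = []
        total = 0
        for seed in range(50):
            cfg = GenerationConfig(seed=seed, precontraction_rate=0.1, p_tms=1.0,
                                   n_blocks=1, block_duration=120.0)
            rng = np.random.default_rng(seed)
            ev = sample_trial_outcomes(cfg, schedule_events(cfg, rng), rng)
            rates.append(1.0 - ev["precontraction"].mean())
            total += len(ev)
        assert np.mean(rates) == pytest.approx(0.9, abs=3 * np.sqrt(0.1 * 0.9 / total))
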