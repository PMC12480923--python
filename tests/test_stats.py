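"""Paired contrasts, cohort descriptors, group aggregation, model fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

from tacsmep.io import load_example_cohort
from tacsmep.phase import circular_difference_deg
from tacsmep.stats import (
    GroupResult,
    cohort_summary,
    efficacy_variability_report,
    fit_phase_modulation,
    group_summary,
    paired_contrast,
)


class TestPairedContrast:
    def test_hand_computed_difference_scores(self):
        """Differences (1, 2, 3): d_z = 2/1 = 2, t = 2*sqrt(3) ~ 3.464,
        p from the t CDF with 2 df ~ 0.0742."""
        res = paired_contrast([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.mean_diff == pytest.approx(2.0)
        assert res.d == pytest.approx(2.0)
        assert res.t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert res.p == pytest.approx(2.0 * sps.t.sf(2.0 * np.sqrt(3.0), df=2), rel=1e-12)
        assert res.p == pytest.approx(0.0742, abs=5e-4)

    def test_identical_inputs_are_degenerate_with_p_one(self):
        res = paired_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.d == 0.0 and res.t == 0.0 and res.p == 1.0
        assert res.degenerate

    def test_constant_nonzero_difference_flagged_undefined(self):
        res = paired_contrast([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.d)

    @settings(deadline=None, max_examples=50)
    @given(
        hnp.arrays(np.float64, (8,), elements=st.floats(-100, 100)),
        hnp.arrays(np.float64, (8,), elements=st.floats(-100, 100)),
    )
    def test_antisymmetry(self, a, b):
        """Swapping conditions negates d and t and keeps p."""
        r1, r2 = paired_contrast(a, b), paired_contrast(b, a)
        if r1.degenerate:
            assert r2.degenerate
            return
        assert r1.d == pytest.approx(-r2.d, rel=1e-9)
        assert r1.t == pytest.approx(-r2.t, rel=1e-9)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)

    def test_agrees_with_scipy_ttest_rel(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.3, 1, 20)
        res = paired_contrast(a, b)
        t, p = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(t, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)


class TestCohortSummary:
    def test_example_cohort_motor_thresholds(self):
        cs = cohort_summary(load_example_cohort())
        assert cs.mt_s01_mean == pytest.approx(68.8, abs=0.05)
        assert cs.mt_s01_sd == pytest.approx(7.54, abs=0.01)
        assert cs.mt_s02_mean == pytest.approx(69.1, abs=0.05)
        assert cs.mt_s02_sd == pytest.approx(7.56, abs=0.01)

    def test_example_cohort_demographics(self):
        cs = cohort_summary(load_example_cohort())
        assert cs.n == 15 and cs.n_female == 10
        assert cs.age_mean == pytest.approx(26.6, abs=0.05)
        assert cs.age_sd == pytest.approx(5.7, abs=0.05)

    def test_single_participant_sd_undefined(self):
        table = load_example_cohort().head(1)
        cs = cohort_summary(table)
        assert cs.n == 1 and np.isnan(cs.age_sd) and np.isnan(cs.mt_s01_sd)

    def test_missing_fields_excluded_with_log(self, caplog):
        table = load_example_cohort().copy()
        table.loc[0, "age"] = np.nan
        with caplog.at_level("WARNING"):
            cs = cohort_summary(table)
        assert cs.n == 14
        assert "excluded" in caplog.text


def _summaries(z_by_bin, cv_by_bin, n_participants=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        medians = {b: 1000 + 300 * z + rng.normal(0, 60) for b, z in z_by_bin.items()}
        vals = np.array(list(medians.values()))
        z = (vals - vals.mean()) / vals.std(ddof=1)
        for (b, _), zi in zip(medians.items(), z):
            rows.append(
                {
                    "participant": f"P{p:02d}",
                    "session": "alpha",
                    "tacs_frequency": 10.0,
                    "bin": b,
                    "n_trials": 30,
                    "median_mep": medians[b],
                    "z_median": zi,
                    "cv": cv_by_bin[b] + rng.normal(0, 0.03),
                    "degenerate": False,
                }
            )
    return pd.DataFrame(rows)


class TestGroupSummary:
    def test_argmax_and_argmin_bins(self):
        summaries = _summaries(
            {"peak": -0.5, "falling": 0.0, "trough": 1.0, "rising": -0.5},
            {"peak": 0.6, "falling": 0.45, "trough": 0.6, "rising": 0.6},
        )
        gr = group_summary(summaries)
        assert isinstance(gr, GroupResult)
        assert gr.argmax_z_bin == "trough"
        assert gr.argmin_cv_bin == "falling"
        assert gr.n_participants == 10
        assert len(gr.contrasts) == 12  # 6 pairs x 2 measures
        assert gr.contrasts["p_holm"].notna().all()

    def test_group_z_means_sum_to_zero(self):
        summaries = _summaries(
            {"peak": -0.4, "falling": 0.0, "trough": 0.7, "rising": -0.3},
            {"peak": 0.6, "falling": 0.5, "trough": 0.6, "rising": 0.6},
        )
        gr = group_summary(summaries)
        assert gr.bin_stats["z_mean"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_refuses_fewer_than_two_complete_participants(self):
        summaries = _summaries({"peak": 0, "falling": 0, "trough": 1, "rising": 0},
                               {"peak": 0.5, "falling": 0.5, "trough": 0.5, "rising": 0.5},
                               n_participants=2)
        summaries.loc[summaries["participant"] == "P00", "z_median"] = np.nan
        with pytest.raises(ValueError, match=">= 2 participants"):
            group_summary(summaries)

    def test_mixed_sessions_refused(self):
        summaries = _summaries({"peak": 0, "falling": 0, "trough": 1, "rising": 0},
                               {"peak": 0.5, "falling": 0.5, "trough": 0.5, "rising": 0.5})
        summaries.loc[0, "session"] = "beta"
        with pytest.raises(ValueError, match="one session"):
            group_summary(summaries)


class TestEfficacyVariabilityReport:
    def test_trough_rightmost_for_alpha_like_cohort(self, tmp_path):
        gr = group_summary(
            _summaries(
                {"peak": -0.5, "falling": 0.0, "trough": 1.0, "rising": -0.5},
                {"peak": 0.6, "falling": 0.45, "trough": 0.6, "rising": 0.6},
            )
        )
        fig = tmp_path / "report.png"
        table = efficacy_variability_report([gr], figure_path=str(fig))
        best = table.loc[table["z_mean"].idxmax(), "bin"]
        assert best == "trough"
        assert fig.exists()
        # trough (max efficacy) and falling (min variability) are both
        # non-dominated
        frontier = set(table.loc[table["on_frontier"], "bin"])
        assert {"trough", "falling"} <= frontier

    def test_single_bin_has_no_frontier(self):
        gr = group_summary(
            _summaries(
                {"peak": -0.5, "falling": 0.0, "trough": 1.0, "rising": -0.5},
                {"peak": 0.6, "falling": 0.45, "trough": 0.6, "rising": 0.6},
            )
        )
        gr.bin_stats.loc[gr.bin_stats["bin"] != "peak", ["z_mean", "cv_mean"]] = np.nan
        table = efficacy_variability_report([gr])
        assert len(table) == 1
        assert not table["on_frontier"].any()


class TestFitPhaseModulation:
    def test_exact_recovery_on_noiseless_trials(self):
        rng = np.random.default_rng(3)
        phases = rng.uniform(0, 360, 200)
        amps = 900.0 * (1 + 0.4 * np.cos(np.radians(phases - 210.0)))
        fit = fit_phase_modulation(phases, amps)
        assert fit.baseline == pytest.approx(900.0, rel=1e-9)
        assert fit.depth == pytest.approx(0.4, abs=1e-9)
        assert fit.preferred_phase_deg == pytest.approx(210.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_median_recovery_at_session_scale_with_default_noise(self):
        """Across replicate 120-trial sessions at depth 0.3 with
        lognormal(0.5) trial noise, the median absolute phase error is
        well inside 20 deg and the median depth error inside 0.1."""
        rng = np.random.default_rng(17)
        phase_errs, depth_errs = [], []
        for _ in range(25):
            targets = np.resize([0.0, 90.0, 180.0, 270.0], 120)
            phases = (targets + rng.normal(0, 10, 120)) % 360
            amps = 1000.0 * (1 + 0.3 * np.cos(np.radians(phases - 180.0)))
            amps = amps * rng.lognormal(0, 0.5, 120)
            fit = fit_phase_modulation(phases, amps)
            phase_errs.append(abs(circular_difference_deg(fit.preferred_phase_deg, 180.0)))
            depth_errs.append(abs(fit.depth - 0.3))
        assert np.median(phase_errs) < 20.0
        assert np.median(depth_errs) < 0.1
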