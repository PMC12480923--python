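"""Group-level statistics: paired contrasts, cohort descriptors, reports.

Effect sizes are paired standardized mean differences on difference
scores, d_z = mean(a - b) / SD(a - b) — the within-subject form of
Cohen's d, for which 0.5 is conventionally a medium effect.  A
pooled-SD variant is available for comparison.  Pairwise p-values are
two-tailed and uncorrected (six contrasts per measure); a
Holm-corrected column is additionally emitted, labelled as an
extension.

The module also provides the pipeline's headline diagnostic: a
least-squares fit of the cosine excitability model
``amplitude = b * (1 + m * cos(theta - phi0))`` to accepted trials,
recovering the preferred phase and modulation depth.  The model is
linear in ``(b, b*m*cos(phi0), b*m*sin(phi0))``, so the least-squares
optimum is found in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phase import BIN_ORDER

__all__ = [
    "ContrastResult",
    "CohortSummary",
    "GroupResult",
    "ModulationFit",
    "paired_contrast",
    "group_summary",
    "cohort_summary",
    "efficacy_variability_report",
    "fit_phase_modulation",
    "paired_t_arrays",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastResult:
    """Paired contrast between two conditions."""

    n: int
    mean_diff: float
    d: float  # paired standardized mean difference (d_z)
    t: float
    p: float
    degenerate: bool  # zero SD of the difference scores


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_female: int
    age_mean: float
    age_sd: float
    mt_s01_mean: float
    mt_s01_sd: float
    mt_s02_mean: float
    mt_s02_sd: float


@dataclass
class GroupResult:
    """Group aggregation for one tACS frequency.

    ``bin_stats`` has one row per phase bin with group mean/SD/SEM of
    the z-scored median amplitude and of the CV; ``contrasts`` holds all
    six pairwise bin contrasts for each measure.
    """

    session: str
    tacs_frequency: float
    n_participants: int
    bin_stats: pd.DataFrame
    contrasts: pd.DataFrame
    argmax_z_bin: str
    argmin_cv_bin: str


@dataclass(frozen=True)
class ModulationFit:
    """Closed-form least-squares fit of the cosine excitability model."""

    baseline: float
    depth: float
    preferred_phase_deg: float
    r2: float


def paired_t_arrays(diffs: np.ndarray, axis: int = -1):
    """Paired t statistics along ``axis`` of an array of difference scores.

    Returns (mean, d_z, t, p, degenerate) arrays; shared kernel behind
    :func:`paired_contrast` and the Monte-Carlo harness so both routes
    use one formula.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[axis]
    if n < 2:
        raise ValueError("paired contrast needs n >= 2 pairs")
    mean = diffs.mean(axis=axis)
    sd = diffs.std(axis=axis, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(degenerate, np.where(mean == 0.0, 0.0, np.nan), mean / sd)
        t = np.where(degenerate, np.where(mean == 0.0, 0.0, np.inf), mean * np.sqrt(n) / sd)
    p = np.where(np.isnan(t), np.nan, 2.0 * sps.t.sf(np.abs(t), df=n - 1))
    return mean, d, t, p, degenerate


def paired_contrast(values_a, values_b, *, pooled_sd: bool = False) -> ContrastResult:
    """Paired two-tailed t-test with a standardized mean difference.

    ``d`` is mean(a - b) / SD(a - b) by default (d_z); with
    ``pooled_sd=True`` the denominator is the pooled SD of the two
    conditions instead.  Identical inputs yield d = 0, t = 0, p = 1 with
    the ``degenerate`` flag set; a non-zero constant difference has
    undefined d (NaN) and is also flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired observations must be 1-D arrays of equal length")
    mean, d, t, p, degenerate = paired_t_arrays(a - b)
    if pooled_sd:
        pooled = np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0)
        d = mean / pooled if pooled > 0 else np.nan
    return ContrastResult(
        n=a.size,
        mean_diff=float(mean),
        d=float(d),
        t=float(t),
        p=float(p),
        degenerate=bool(degenerate),
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (emitted as a labelled extension)."""
    from statsmodels.stats.multitest import multipletests

    mask = ~np.isnan(pvals)
    adjusted = np.full_like(pvals, np.nan, dtype=float)
    if mask.any():
        adjusted[mask] = multipletests(pvals[mask], method="holm")[1]
    return adjusted


def group_summary(bin_summaries: pd.DataFrame) -> GroupResult:
    """Aggregate one frequency's per-participant bin summaries.

    Expects the output of :func:`tacsmep.mep.summarize_bins` restricted
    to a single session label.  Z-median statistics and contrasts use
    only participants with complete, non-degenerate bin profiles; CV
    contrasts use participants with both bins' CV defined.  Requires at
    least two complete participants.
    """
    sessions = bin_summaries["session"].unique()
    if len(sessions) != 1:
        raise ValueError("group_summary expects summaries for exactly one session")
    session = sessions[0]
    freq = float(bin_summaries["tacs_frequency"].iloc[0])

    z_wide = bin_summaries.pivot(index="participant", columns="bin", values="z_median")[
        list(BIN_ORDER)
    ]
    cv_wide = bin_summaries.pivot(index="participant", columns="bin", values="cv")[
        list(BIN_ORDER)
    ]
    complete = z_wide.dropna()
    if len(complete) < 2:
        raise ValueError(
            f"group analysis needs >= 2 participants with all four bins defined; "
            f"got {len(complete)}"
        )
    if len(complete) < len(z_wide):
        dropped = sorted(set(z_wide.index) - set(complete.index))
        logger.info("excluded from group z-analysis (incomplete bins): %s", dropped)

    rows = []
    for label in BIN_ORDER:
        z = complete[label].to_numpy()
        cv = cv_wide[label].dropna().to_numpy()
        rows.append(
            {
                "bin": label,
                "n_z": z.size,
                "z_mean": z.mean(),
                "z_sd": z.std(ddof=1),
                "z_sem": z.std(ddof=1) / np.sqrt(z.size),
                "n_cv": cv.size,
                "cv_mean": cv.mean() if cv.size else np.nan,
                "cv_sd": cv.std(ddof=1) if cv.size >= 2 else np.nan,
                "cv_sem": cv.std(ddof=1) / np.sqrt(cv.size) if cv.size >= 2 else np.nan,
            }
        )
    bin_stats = pd.DataFrame(rows)

    contrast_rows = []
    for measure, wide in (("z_median", complete), ("cv", cv_wide)):
        for a, b in combinations(BIN_ORDER, 2):
            paired = wide[[a, b]].dropna()
            if len(paired) < 2:
                contrast_rows.append(
                    {
                        "measure": measure,
                        "bin_a": a,
                        "bin_b": b,
                        "n": len(paired),
                        "mean_diff": np.nan,
                        "d": np.nan,
                        "t": np.nan,
                        "p": np.nan,
                        "degenerate": True,
                    }
                )
                continue
            res = paired_contrast(paired[a].to_numpy(), paired[b].to_numpy())
            contrast_rows.append(
                {
                    "measure": measure,
                    "bin_a": a,
                    "bin_b": b,
                    "n": res.n,
                    "mean_diff": res.mean_diff,
                    "d": res.d,
                    "t": res.t,
                    "p": res.p,
                    "degenerate": res.degenerate,
                }
            )
    contrasts = pd.DataFrame(contrast_rows)
    contrasts["p_holm"] = np.nan
    for measure in ("z_median", "cv"):
        sel = contrasts["measure"] == measure
        contrasts.loc[sel, "p_holm"] = _holm(contrasts.loc[sel, "p"].to_numpy())

    return GroupResult(
        session=session,
        tacs_frequency=freq,
        n_participants=len(complete),
        bin_stats=bin_stats,
        contrasts=contrasts,
        argmax_z_bin=bin_stats.loc[bin_stats["z_mean"].idxmax(), "bin"],
        argmin_cv_bin=bin_stats.loc[bin_stats["cv_mean"].idxmin(), "bin"],
    )


def cohort_summary(participants: pd.DataFrame) -> CohortSummary:
    """Cohort descriptors: sex counts, mean/sample-SD age and MT per session.

    Rows with missing age/MT fields are excluded with a log message.
    With a single participant the SDs are undefined (NaN).
    """
    required = ["age", "mt_s01", "mt_s02"]
    ok = participants.dropna(subset=required)
    if len(ok) < len(participants):
        logger.warning(
            "cohort_summary: excluded %d row(s) with missing fields",
            len(participants) - len(ok),
        )
    if ok.empty:
        raise ValueError("cohort_summary needs >= 1 complete participant")

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) >= 2 else float("nan")

    return CohortSummary(
        n=len(ok),
        n_female=int((ok["sex"] == "F").sum()),
        age_mean=float(ok["age"].mean()),
        age_sd=_sd(ok["age"]),
        mt_s01_mean=float(ok["mt_s01"].mean()),
        mt_s01_sd=_sd(ok["mt_s01"]),
        mt_s02_mean=float(ok["mt_s02"].mean()),
        mt_s02_sd=_sd(ok["mt_s02"]),
    )


def efficacy_variability_report(
    group_results, figure_path: Optional[str] = None
) -> pd.DataFrame:
    """Efficacy-versus-variability summary across phase bins.

    For each frequency, one point per bin at (mean z-scored median
    amplitude, mean CV) with SEM error bars.  A bin is on the
    efficacy-variability frontier when no other bin offers both higher
    mean amplitude and lower mean CV (Pareto sense: maximise efficacy,
    minimise variability).  Optionally renders a scatter figure.
    """
    results = list(group_results)
    if not results:
        raise ValueError("need at least one GroupResult")
    rows = []
    for gr in results:
        stats = gr.bin_stats.set_index("bin")
        present = stats.dropna(subset=["z_mean", "cv_mean"])
        for label in present.index:
            z, cv = present.loc[label, "z_mean"], present.loc[label, "cv_mean"]
            dominated = any(
                (present.loc[o, "z_mean"] > z) and (present.loc[o, "cv_mean"] < cv)
                for o in present.index
                if o != label
            )
            rows.append(
                {
                    "session": gr.session,
                    "tacs_frequency": gr.tacs_frequency,
                    "bin": label,
                    "z_mean": z,
                    "z_sem": present.loc[label, "z_sem"],
                    "cv_mean": cv,
                    "cv_sem": present.loc[label, "cv_sem"],
                    "on_frontier": (not dominated) and len(present) > 1,
                }
            )
    report = pd.DataFrame(rows)

    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(
            1, len(results), figsize=(5 * len(results), 4), squeeze=False
        )
        for ax, gr in zip(axes[0], results):
            sub = report[report["session"] == gr.session]
            ax.errorbar(
                sub["z_mean"],
                sub["cv_mean"],
                xerr=sub["z_sem"],
                yerr=sub["cv_sem"],
                fmt="o",
                capsize=3,
            )
            for row in sub.itertuples():
                ax.annotate(row.bin, (row.z_mean, row.cv_mean), textcoords="offset points", xytext=(5, 5))
            ax.set_xlabel("mean z-scored median MEP amplitude")
            ax.set_ylabel("mean CV")
            ax.set_title(f"{gr.session} ({gr.tacs_frequency:g} Hz), n={gr.n_participants}")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return report


def fit_phase_modulation(phase_deg, amplitude) -> ModulationFit:
    """Recover the cosine excitability model from (phase, amplitude) trials.

    Fits ``amplitude = b * (1 + m * cos(theta - phi0))`` by exact least
    squares via the linear reparameterisation
    ``b + c1*cos(theta) + c2*sin(theta)`` with ``m = |(c1, c2)| / b``
    and ``phi0 = atan2(c2, c1)``.  With multiplicative amplitude noise
    the baseline estimate absorbs the noise mean; the phase and relative
    depth are unaffected.
    """
    theta = np.radians(np.asarray(phase_deg, dtype=float))
    y = np.asarray(amplitude, dtype=float)
    if theta.shape != y.shape or theta.ndim != 1:
        raise ValueError("phase_deg and amplitude must be 1-D arrays of equal length")
    if y.size < 4:
        raise ValueError("need >= 4 trials to fit the three-parameter model")
    design = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    b, c1, c2 = coef
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return ModulationFit(
        baseline=float(b),
        depth=float(np.hypot(c1, c2) / b) if b != 0 else float("nan"),
        preferred_phase_deg=float(np.degrees(np.arctan2(c2, c1)) % 360.0),
        r2=max(0.0, min(1.0, r2)),
    )
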