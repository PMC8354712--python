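"""End-to-end orchestration: traces -> choice records -> binned analyses -> report.

This is the programmatic backbone behind the command-line interface: it runs
kinematic event detection and choice classification over a cohort, then
assembles every analysis the task supports — binwise condition contrasts, the
95%-criterion delay, CTRL low-cost-preference tests, configuration- and
block-wise comparisons, AIC-selected mixed models, and earnings in both
points modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .binning import (BinnedSuccessTable, DelayEstimate, bin_success,
                      binwise_contrast, estimate_delay, grouped_success,
                      initial_vs_final)
from .choices import (RESCUE_RADIUS_CM, TIMING_WINDOW_MS, evaluate_trial,
                      exclusion_summary, records_to_frame)
from .design import START_RADIUS_CM, Condition, TimingConstants
from .errors import (InsufficientTraceError, NoMovementError, NoStopError,
                     PreconditionError)
from .kinematics import SPEED_THRESHOLD_CM_S, summarize
from .stats import MixedModelSpec, TestResult, fit_mixed_logistic, \
    paired_test, select_by_aic, wilcoxon_vs_value
from .synthetic import CohortData, SubjectData

log = logging.getLogger("reachcost")


@dataclass(frozen=True)
class AnalysisParams:
    """Every analysis constant, exposed as a named key with its task default."""

    start_radius_cm: float = START_RADIUS_CM
    speed_threshold_cm_s: float = SPEED_THRESHOLD_CM_S
    rescue_radius_cm: float = RESCUE_RADIUS_CM
    timing_window_ms: float = TIMING_WINDOW_MS
    rt_min_ms: float = 200.0
    rt_max_ms: float = 460.0
    bin_width_ms: float = 20.0
    delay_criterion_pct: float = 95.0
    grouped_rt_max_ms: float = 350.0
    alpha: float = 0.05
    fit_mixed_models: bool = True

    def __post_init__(self) -> None:
        if self.rt_min_ms >= self.rt_max_ms:
            raise PreconditionError("rt_min must be below rt_max")
        span = self.rt_max_ms - self.rt_min_ms
        if abs(span / self.bin_width_ms - round(span / self.bin_width_ms)) > 1e-9:
            raise PreconditionError("bin width must divide the RT range")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisParams":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data.get("analysis", data))


# ---------------------------------------------------------------------------
# Trace -> record processing
# ---------------------------------------------------------------------------

def process_subject(subject: SubjectData, params: AnalysisParams = AnalysisParams(),
                    timing: TimingConstants = TimingConstants()) -> pd.DataFrame:
    """Run kinematics + choice classification over one subject's session."""
    records = []
    metas = []
    n_unprocessable = 0
    for meta, trace in zip(subject.schedule, subject.traces):
        target_onset_abs = timing.go_ms + meta.target_onset_ms
        try:
            summary = summarize(trace, meta.targets, target_onset_abs,
                                start_radius=params.start_radius_cm,
                                speed_threshold=params.speed_threshold_cm_s)
        except (NoMovementError, NoStopError, InsufficientTraceError) as exc:
            n_unprocessable += 1
            log.debug("trial %d unprocessable: %s", meta.trial_id, exc)
            continue
        records.append(evaluate_trial(summary, meta, timing.go_ms,
                                      rescue_radius=params.rescue_radius_cm,
                                      timing_window_ms=params.timing_window_ms))
        metas.append(meta)
    if n_unprocessable:
        log.info("subject %d: %d traces without detectable events dropped",
                 subject.subject, n_unprocessable)
    return records_to_frame(records, metas, subject.subject)


def process_cohort(cohort: CohortData,
                   params: AnalysisParams = AnalysisParams()) -> pd.DataFrame:
    """Per-trial choice records for every subject, as one tidy frame."""
    frames = [process_subject(sub, params, cohort.config.timing)
              for sub in cohort.subjects]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    params: AnalysisParams
    n_trials: int
    exclusions: pd.DataFrame
    binned_initial: BinnedSuccessTable
    binned_final: BinnedSuccessTable
    delay: DelayEstimate
    contrast_cong_incong: pd.DataFrame
    contrast_incong_rhc: pd.DataFrame
    ctrl_lc_tests: pd.DataFrame
    initial_vs_final_incong: pd.DataFrame
    configuration_rates: pd.DataFrame
    configuration_tests: pd.DataFrame
    block_rates: pd.DataFrame
    earnings: pd.DataFrame
    earnings_test: Optional[TestResult]
    mixed_fits: dict = field(default_factory=dict)


def ctrl_lc_preference(records: pd.DataFrame) -> pd.DataFrame:
    """Per-configuration one-sample tests of LC-choice proportion vs 50%.

    CTRL trials carry no unique rewarded target, so choice bias is measured as
    the percentage of valid CTRL 2T trials whose initial choice was the
    low-cost target, tested against chance with a signed-rank test and
    Bonferroni correction over the four configurations.
    """
    ctrl = records[records["condition"].isin(["CTRL_REWARDED", "CTRL_UNREWARDED"])
                   & records["valid"]]
    rows = []
    confs = sorted(c for c in ctrl["configuration"].unique() if c)
    for conf in confs:
        sub = ctrl[ctrl["configuration"] == conf]
        props = (sub.assign(lc=sub["initial_cost_class"] == "LC")
                 .groupby("subject")["lc"].mean() * 100.0)
        if len(props) < 5:
            continue
        res = wilcoxon_vs_value(props.to_numpy(), 50.0).corrected(len(confs))
        rows.append({"configuration": conf, "n_subjects": len(props),
                     "mean_lc_pct": float(props.mean()), "W": res.statistic_value,
                     "p_raw": res.p_raw, "p_corrected": res.p_corrected,
                     "effect_size_d": res.effect_size_d})
    return pd.DataFrame(rows, columns=["configuration", "n_subjects", "mean_lc_pct",
                                       "W", "p_raw", "p_corrected", "effect_size_d"])


def configuration_contrasts(config_rates: pd.DataFrame) -> pd.DataFrame:
    """CONG-vs-INCONG paired tests per target configuration (Bonferroni m=4)."""
    rows = []
    groups = sorted(config_rates["group"].unique())
    for conf in groups:
        cell = config_rates[config_rates["group"] == conf]
        a = cell[cell.condition == "CONG"].set_index("subject")["rate"]
        b = cell[cell.condition == "INCONG"].set_index("subject")["rate"]
        common = a.index.intersection(b.index)
        if len(common) < 3:
            continue
        res = paired_test(a.loc[common].to_numpy(),
                          b.loc[common].to_numpy()).corrected(len(groups))
        rows.append({"configuration": conf, "n_subjects": len(common),
                     "mean_diff": float((a.loc[common] - b.loc[common]).mean()),
                     "statistic_name": res.statistic_name,
                     "statistic": res.statistic_value, "p_raw": res.p_raw,
                     "p_corrected": res.p_corrected,
                     "effect_size_d": res.effect_size_d})
    return pd.DataFrame(rows, columns=["configuration", "n_subjects", "mean_diff",
                                       "statistic_name", "statistic", "p_raw",
                                       "p_corrected", "effect_size_d"])


def earnings_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject total points by condition, in raw and MT-corrected modes."""
    out = (records.groupby(["subject", "condition"])[
        ["points_raw", "points_mt_corrected"]].sum().reset_index())
    return out


def earnings_contrast(earnings: pd.DataFrame) -> Optional[TestResult]:
    """CONG vs INCONG total points per subject, MT correction removed."""
    a = earnings[earnings.condition == "CONG"].set_index("subject")["points_raw"]
    b = earnings[earnings.condition == "INCONG"].set_index("subject")["points_raw"]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        return None
    return paired_test(a.loc[common].to_numpy(), b.loc[common].to_numpy())


def _success_glmm(table: BinnedSuccessTable) -> dict:
    """Binomial mixed models on per-subject-per-bin proportions, AIC-selected."""
    data = table.subject_rates.copy()
    data["prop"] = data["rate"] / 100.0
    null_spec = MixedModelSpec("prop ~ 1", family="binomial", weights="n_trials")
    full_spec = MixedModelSpec("prop ~ condition + C(bin)", family="binomial",
                               weights="n_trials")
    fits = [fit_mixed_logistic(null_spec, data), fit_mixed_logistic(full_spec, data)]
    return {"candidates": fits, "selected": select_by_aic(fits)}


def _block_glmm(block_rates: pd.DataFrame) -> dict:
    """Gaussian mixed models for the learning analysis (congruence x block)."""
    data = block_rates.copy()
    fits = [fit_mixed_logistic(
                MixedModelSpec("rate ~ condition", family="gaussian"), data),
            fit_mixed_logistic(
                MixedModelSpec("rate ~ condition + C(group)", family="gaussian"), data)]
    return {"candidates": fits, "selected": select_by_aic(fits)}


def analyze_records(records: pd.DataFrame,
                    params: AnalysisParams = AnalysisParams()) -> AnalysisReport:
    """Every analysis stage on a per-trial record frame."""
    kw = dict(rt_min=params.rt_min_ms, rt_max=params.rt_max_ms,
              width=params.bin_width_ms)
    reward_conds = [c.value for c in
                    (Condition.CONG, Condition.INCONG, Condition.R_LC, Condition.R_HC)]
    binned_i = bin_success(records, "success_initial", conditions=reward_conds, **kw)
    binned_f = bin_success(records, "success_final", conditions=reward_conds, **kw)
    delay = estimate_delay(binned_i, "CONG", "INCONG", params.delay_criterion_pct)
    config_rates = grouped_success(records, "configuration",
                                   rt_max=params.grouped_rt_max_ms,
                                   rt_min=params.rt_min_ms)
    block_rates = grouped_success(records, "block",
                                  rt_max=params.grouped_rt_max_ms,
                                  rt_min=params.rt_min_ms)
    earnings = earnings_table(records)
    mixed = {}
    if params.fit_mixed_models:
        mixed["success"] = _success_glmm(binned_i)
        if block_rates["group"].nunique() > 1:
            mixed["block"] = _block_glmm(block_rates)

    return AnalysisReport(
        params=params, n_trials=len(records),
        exclusions=exclusion_summary(records),
        binned_initial=binned_i, binned_final=binned_f, delay=delay,
        contrast_cong_incong=binwise_contrast(binned_i, "CONG", "INCONG"),
        contrast_incong_rhc=binwise_contrast(binned_i, "R_HC", "INCONG"),
        ctrl_lc_tests=ctrl_lc_preference(records),
        initial_vs_final_incong=initial_vs_final(records, "INCONG", **kw),
        configuration_rates=config_rates,
        configuration_tests=configuration_contrasts(config_rates),
        block_rates=block_rates,
        earnings=earnings, earnings_test=earnings_contrast(earnings),
        mixed_fits=mixed)


# ---------------------------------------------------------------------------
# Report rendering / output
# ---------------------------------------------------------------------------

def render_report(report: AnalysisReport) -> str:
    from .choices import convert_to_currency

    lines = ["# reachcost analysis report", ""]
    lines.append(f"trials analysed: {report.n_trials}")
    lines.append("exclusion accounting:")
    for row in report.exclusions.itertuples(index=False):
        lines.append(f"  {row.reason}: {row.n_trials}")
    lines.append("")

    d = report.delay
    lines.append("## 95%-criterion delay (CONG vs INCONG)")
    if d.delay_ms is None:
        lines.append("delay undefined: at least one condition never reaches the criterion "
                     f"(qualifying bins: {d.qualifying_bin_a}, {d.qualifying_bin_b})")
    else:
        cens = " (left-censored at the first bin)" if d.censored_a else ""
        lines.append(f"delay = {d.delay_ms:.0f} +- {d.uncertainty_ms:.0f} ms{cens}")
    lines.append("")

    lines.append("## Binwise CONG - INCONG contrast (initial choice, % points)")
    for row in report.contrast_cong_incong.itertuples(index=False):
        lines.append(f"  [{row.bin_low:.0f},{row.bin_high:.0f}) "
                     f"diff={row.mean_diff:+6.1f}  {row.statistic_name}="
                     f"{row.statistic:6.2f}  p_corr={row.p_corrected:.4g}")
    lines.append("")

    lines.append("## CTRL low-cost-target preference (vs 50%)")
    for row in report.ctrl_lc_tests.itertuples(index=False):
        lines.append(f"  {row.configuration}: mean={row.mean_lc_pct:5.1f}%  "
                     f"W={row.W:.0f}  p_corr={row.p_corrected:.4g}  d={row.effect_size_d:.2f}")
    lines.append("")

    gain = report.initial_vs_final_incong["gain"]
    if len(gain):
        lines.append(f"## Initial vs final choice (INCONG): mean gain "
                     f"{gain.mean():+.2f} % points over {len(gain)} bins")
    lines.append("")

    lines.append("## Configuration-wise CONG vs INCONG (RT < grouped max)")
    for row in report.configuration_tests.itertuples(index=False):
        lines.append(f"  {row.configuration}: diff={row.mean_diff:+6.1f}  "
                     f"{row.statistic_name}={row.statistic:6.2f}  "
                     f"p_corr={row.p_corrected:.4g}")
    lines.append("")

    totals = report.earnings.groupby("subject")[["points_raw", "points_mt_corrected"]].sum()
    mean_raw = float(totals["points_raw"].mean())
    mean_corr = float(totals["points_mt_corrected"].mean())
    lines.append("## Earnings")
    lines.append(f"  mean total points/subject: raw={mean_raw:.1f} "
                 f"(${convert_to_currency(max(0.0, mean_raw)):.2f}), "
                 f"mt_corrected={mean_corr:.1f} "
                 f"(${convert_to_currency(max(0.0, mean_corr)):.2f})")
    if report.earnings_test is not None:
        t = report.earnings_test
        lines.append(f"  CONG - INCONG total points (raw): "
                     f"{t.statistic_name}={t.statistic_value:.2f}  p={t.p_raw:.4g}  "
                     f"d={t.effect_size_d:.2f}")
    lines.append("")

    for name, fits in report.mixed_fits.items():
        sel = fits["selected"]
        lines.append(f"## Mixed model ({name}): selected {sel.spec.formula!r} "
                     f"[{sel.spec.family}]")
        lines.append(f"  AIC={sel.aic:.1f}  BIC={sel.bic:.1f}  "
                     f"marginal R2={sel.marginal_r2:.2f}  "
                     f"conditional R2={sel.conditional_r2:.2f}  "
                     f"converged={sel.converged}")
        for row in sel.omnibus.itertuples(index=False):
            lines.append(f"    {row.term}: chi2({row.df})={row.wald_chi2:.1f}  "
                         f"p={row.p:.4g}")
    lines.append("")
    return "\n".join(lines)


def write_report(report: AnalysisReport, out_dir) -> None:
    """Write all tidy CSVs and the text report to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.binned_initial.subject_rates.to_csv(out / "binned_subject_initial.csv", index=False)
    report.binned_initial.group.to_csv(out / "binned_group_initial.csv", index=False)
    report.binned_final.group.to_csv(out / "binned_group_final.csv", index=False)
    report.contrast_cong_incong.to_csv(out / "contrast_cong_incong.csv", index=False)
    report.contrast_incong_rhc.to_csv(out / "contrast_incong_rhc.csv", index=False)
    report.ctrl_lc_tests.to_csv(out / "ctrl_lc_tests.csv", index=False)
    report.initial_vs_final_incong.to_csv(out / "initial_vs_final_incong.csv", index=False)
    report.configuration_rates.to_csv(out / "configuration_rates.csv", index=False)
    report.configuration_tests.to_csv(out / "configuration_tests.csv", index=False)
    report.block_rates.to_csv(out / "block_rates.csv", index=False)
    report.earnings.to_csv(out / "earnings.csv", index=False)
    report.exclusions.to_csv(out / "exclusions.csv", index=False)
    (out / "report.txt").write_text(render_report(report))
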