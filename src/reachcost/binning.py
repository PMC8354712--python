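"""RT-binned success curves, the 95%-criterion delay, and condition contrasts.

Success rates are computed per subject in thirteen 20-ms reaction-time bins
spanning 200-460 ms ([200,220), ..., [440,460]; the last bin is closed).  Group
curves are unweighted means of subject rates with a t-based 95% confidence
interval across subjects.  The delay between two conditions is read off the
earliest bin per condition whose group ci95 contains an absolute success
criterion (95% by default): when the faster condition already qualifies in the
earliest analysable bin its qualifying time is left-censored at the bin's lower
edge, and the slower condition is scored at its qualifying bin's midpoint, so
the estimate carries a half-bin (+-10 ms) uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PreconditionError
from .stats import paired_test

RT_MIN_MS = 200.0
RT_MAX_MS = 460.0
BIN_WIDTH_MS = 20.0

#: Absolute success-rate criterion (%) for the delay analysis.
DELAY_CRITERION_PCT = 95.0


def bin_edges(rt_min: float = RT_MIN_MS, rt_max: float = RT_MAX_MS,
              width: float = BIN_WIDTH_MS) -> np.ndarray:
    n = (rt_max - rt_min) / width
    if abs(n - round(n)) > 1e-9:
        raise PreconditionError("bin width must divide the RT range")
    return rt_min + width * np.arange(int(round(n)) + 1)


def bin_index(rt: float, edges: Optional[np.ndarray] = None) -> Optional[int]:
    """Half-open bin assignment; the last bin includes its upper edge.

    Returns None for RTs outside the analysis range.
    """
    if edges is None:
        edges = bin_edges()
    if rt < edges[0] or rt > edges[-1]:
        return None
    i = int(np.searchsorted(edges, rt, side="right")) - 1
    return min(i, len(edges) - 2)


def _ci95(values: np.ndarray) -> tuple[float, float]:
    """Two-sided 95% CI of the mean: t(0.975, n-1) x SEM across subjects."""
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return np.nan, np.nan
    half = float(sps.t.ppf(0.975, n - 1) * np.std(values, ddof=1) / np.sqrt(n))
    return mean - half, mean + half


@dataclass(frozen=True)
class BinnedSuccessTable:
    """Subject- and group-level success rates by condition and RT bin.

    ``subject_rates``: tidy frame (subject, condition, bin, bin_low, bin_high,
    rate [%], n_trials), one row per non-empty cell.  ``group``: per
    condition x bin the unweighted mean of subject rates with its t-based 95%
    CI and the number of contributing subjects.  Empty subject cells are
    absent, not imputed as zero.
    """

    subject_rates: pd.DataFrame
    group: pd.DataFrame
    edges: np.ndarray
    value_col: str

    def group_mean(self, condition: str, bin_idx: int) -> float:
        sel = self.group[(self.group.condition == condition) & (self.group.bin == bin_idx)]
        return float(sel["mean"].iloc[0]) if len(sel) else np.nan


def bin_success(records: pd.DataFrame, value_col: str = "success_initial",
                conditions: Optional[list[str]] = None,
                rt_min: float = RT_MIN_MS, rt_max: float = RT_MAX_MS,
                width: float = BIN_WIDTH_MS) -> BinnedSuccessTable:
    """Build the RT-binned success table from a per-trial record frame.

    Only valid trials with a defined success flag and RT inside [rt_min,
    rt_max] contribute (trials faster than 200 ms are too sparse to analyse
    and are dropped).  Rates are percentages of successful trials per subject,
    condition and bin.
    """
    edges = bin_edges(rt_min, rt_max, width)
    df = records[records["valid"] & records[value_col].notna()].copy()
    df[value_col] = df[value_col].astype(bool)
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    df = df[(df["rt_ms"] >= edges[0]) & (df["rt_ms"] <= edges[-1])]
    idx = np.minimum(np.searchsorted(edges, df["rt_ms"].to_numpy(), side="right") - 1,
                     len(edges) - 2)
    df["bin"] = idx

    grouped = (df.groupby(["subject", "condition", "bin"], sort=True)[value_col]
               .agg(successes="sum", n_trials="count").reset_index())
    grouped["rate"] = 100.0 * grouped["successes"] / grouped["n_trials"]
    grouped["bin_low"] = edges[grouped["bin"]]
    grouped["bin_high"] = edges[grouped["bin"] + 1]
    subject_rates = grouped[["subject", "condition", "bin", "bin_low", "bin_high",
                             "rate", "n_trials"]]

    rows = []
    for (cond, b), cell in subject_rates.groupby(["condition", "bin"], sort=True):
        vals = cell["rate"].to_numpy()
        lo, hi = _ci95(vals)
        rows.append({"condition": cond, "bin": int(b),
                     "bin_low": edges[int(b)], "bin_high": edges[int(b) + 1],
                     "mean": float(np.mean(vals)), "ci_low": lo, "ci_high": hi,
                     "n_subjects": len(vals)})
    group = pd.DataFrame(rows, columns=["condition", "bin", "bin_low", "bin_high",
                                        "mean", "ci_low", "ci_high", "n_subjects"])
    return BinnedSuccessTable(subject_rates=subject_rates, group=group,
                              edges=edges, value_col=value_col)


@dataclass(frozen=True)
class DelayEstimate:
    criterion: float
    condition_a: str
    condition_b: str
    qualifying_bin_a: Optional[int]
    qualifying_bin_b: Optional[int]
    censored_a: bool
    delay_ms: Optional[float]
    uncertainty_ms: float


def _qualifying_bin(table: BinnedSuccessTable, condition: str,
                    criterion: float) -> Optional[int]:
    g = table.group[table.group.condition == condition].sort_values("bin")
    if not len(g):
        raise PreconditionError(f"condition {condition!r} absent from the table")
    ok = g[(g.ci_low <= criterion) & (criterion <= g.ci_high)]
    return int(ok["bin"].iloc[0]) if len(ok) else None


def estimate_delay(table: BinnedSuccessTable, cond_a: str, cond_b: str,
                   criterion: float = DELAY_CRITERION_PCT) -> DelayEstimate:
    """Extra RT needed by ``cond_b`` to reach the criterion relative to ``cond_a``.

    Each condition qualifies at the earliest bin whose group ci95 contains the
    criterion.  If ``cond_a`` qualifies in the earliest analysable bin its true
    qualifying time is left-censored, so it is scored at the bin's lower edge;
    otherwise both conditions are scored at bin midpoints.  A condition that
    never qualifies leaves the delay undefined (None) rather than raising.
    """
    bin_a = _qualifying_bin(table, cond_a, criterion)
    bin_b = _qualifying_bin(table, cond_b, criterion)
    edges = table.edges
    censored = bin_a == 0
    delay = None
    if bin_a is not None and bin_b is not None:
        mid_b = float((edges[bin_b] + edges[bin_b + 1]) / 2)
        if censored:
            delay = mid_b - float(edges[0])
        else:
            mid_a = float((edges[bin_a] + edges[bin_a + 1]) / 2)
            delay = mid_b - mid_a
    return DelayEstimate(criterion=criterion, condition_a=cond_a, condition_b=cond_b,
                         qualifying_bin_a=bin_a, qualifying_bin_b=bin_b,
                         censored_a=censored, delay_ms=delay,
                         uncertainty_ms=float(BIN_WIDTH_MS / 2))


def binwise_contrast(table: BinnedSuccessTable, cond_a: str, cond_b: str,
                     correction_m: Optional[int] = None) -> pd.DataFrame:
    """Paired per-bin contrast of two conditions' subject success rates.

    For each bin, subjects contributing to both conditions are paired; the
    mean difference (a - b, percentage points) is tested with the
    normality-gated paired test and Bonferroni-corrected across the tested
    bins.  Bins with fewer than two paired subjects are skipped.
    """
    sub = table.subject_rates
    rows = []
    n_bins = len(table.edges) - 1
    for b in range(n_bins):
        a = sub[(sub.condition == cond_a) & (sub.bin == b)].set_index("subject")["rate"]
        bb = sub[(sub.condition == cond_b) & (sub.bin == b)].set_index("subject")["rate"]
        common = a.index.intersection(bb.index)
        if len(common) < 3:  # Shapiro-Wilk gate needs at least 3 pairs
            continue
        res = paired_test(a.loc[common].to_numpy(), bb.loc[common].to_numpy())
        rows.append({"bin": b, "bin_low": table.edges[b], "bin_high": table.edges[b + 1],
                     "n_subjects": len(common),
                     "mean_diff": float((a.loc[common] - bb.loc[common]).mean()),
                     "statistic_name": res.statistic_name,
                     "statistic": res.statistic_value, "p_raw": res.p_raw,
                     "effect_size_d": res.effect_size_d})
    out = pd.DataFrame(rows, columns=["bin", "bin_low", "bin_high", "n_subjects",
                                      "mean_diff", "statistic_name", "statistic",
                                      "p_raw", "effect_size_d"])
    m = correction_m if correction_m is not None else len(out)
    out["p_corrected"] = np.minimum(1.0, out["p_raw"] * max(m, 1))
    return out


def initial_vs_final(records: pd.DataFrame, condition: str,
                     **kwargs) -> pd.DataFrame:
    """Per-bin gain of final-choice over initial-choice success in one condition.

    Runs :func:`bin_success` on both success flags and differences the group
    means bin by bin (final - initial, percentage points).
    """
    t_init = bin_success(records, "success_initial", conditions=[condition], **kwargs)
    t_fin = bin_success(records, "success_final", conditions=[condition], **kwargs)
    gi = t_init.group.set_index("bin")["mean"]
    gf = t_fin.group.set_index("bin")["mean"]
    common = gi.index.intersection(gf.index)
    return pd.DataFrame({"bin": common, "initial": gi.loc[common].to_numpy(),
                         "final": gf.loc[common].to_numpy(),
                         "gain": (gf.loc[common] - gi.loc[common]).to_numpy()})


def grouped_success(records: pd.DataFrame, grouping: str,
                    conditions: tuple[str, str] = ("CONG", "INCONG"),
                    rt_max: float = 350.0, rt_min: float = RT_MIN_MS) -> pd.DataFrame:
    """Per-subject success rates by configuration or block, for short-RT trials.

    Used for the configuration-wise (visuo-attentional bias) and block-wise
    (learning) analyses, which restrict to RTs below 350 ms where the motor
    cost bias operates.  Returns a tidy frame (subject, group, condition, rate,
    n_trials).
    """
    if grouping not in ("configuration", "block"):
        raise PreconditionError(f"unknown grouping {grouping!r}")
    df = records[records["valid"] & records["success_initial"].notna()
                 & records["condition"].isin(conditions)
                 & (records["rt_ms"] >= rt_min) & (records["rt_ms"] < rt_max)].copy()
    df["success_initial"] = df["success_initial"].astype(bool)
    out = (df.groupby(["subject", grouping, "condition"])["success_initial"]
           .agg(successes="sum", n_trials="count").reset_index())
    out["rate"] = 100.0 * out["successes"] / out["n_trials"]
    return out.rename(columns={grouping: "group"})[
        ["subject", "group", "condition", "rate", "n_trials"]]


def plot_success_curves(table: BinnedSuccessTable, path=None, ax=None):
    """Success-rate-vs-RT curves with ci95 ribbons, one line per condition."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mids = (table.edges[:-1] + table.edges[1:]) / 2
    for cond, g in table.group.groupby("condition"):
        g = g.sort_values("bin")
        x = mids[g["bin"].to_numpy()]
        ax.plot(x, g["mean"], marker="o", label=cond)
        ax.fill_between(x, g["ci_low"], g["ci_high"], alpha=0.2)
    ax.set_xlabel("RT (ms)")
    ax.set_ylabel("success rate (%)")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
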