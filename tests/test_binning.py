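"""RT binning, success tables, the delay criterion, and contrasts."""

import numpy as np
import pandas as pd
import pytest

from reachcost.binning import (BinnedSuccessTable, bin_edges, bin_index,
                               bin_success, binwise_contrast, estimate_delay,
                               grouped_success, initial_vs_final)
from reachcost.errors import PreconditionError


def records_frame(rows):
    df = pd.DataFrame(rows)
    for col, default in [("valid", True), ("success_final", None),
                         ("configuration", "CONF1"), ("block", 1), ("kind", "2T")]:
        if col not in df:
            df[col] = default
    return df


def simulate_records(rng, p_by_bin, n_per_bin, subjects, condition="CONG"):
    rows = []
    edges = bin_edges()
    for s in range(subjects):
        for b, p in enumerate(p_by_bin):
            rts = rng.uniform(edges[b], edges[b + 1] - 1e-9, n_per_bin)
            hits = rng.random(n_per_bin) < p
            for rt, hit in zip(rts, hits):
                rows.append({"subject": s, "condition": condition, "rt_ms": rt,
                             "success_initial": bool(hit)})
    return records_frame(rows)


class TestBinAssignment:
    def test_matches_interval_scan(self):
        """10,000 random RTs vs a brute-force scan over the 13 intervals."""
        rng = np.random.default_rng(7)
        edges = bin_edges()
        mismatches = 0
        for rt in rng.uniform(150, 500, 10_000):
            got = bin_index(rt)
            want = None
            for i in range(13):
                lo, hi = edges[i], edges[i + 1]
                if (lo <= rt < hi) or (i == 12 and rt == hi):
                    want = i
            mismatches += got != want
        assert mismatches == 0

    @pytest.mark.parametrize("rt,idx", [
        (200, 0), (219.99, 0), (220, 1), (460, 12), (199.9, None), (460.1, None),
    ])
    def test_edges(self, rt, idx):
        assert bin_index(rt) == idx


class TestBinSuccess:
    def test_perfect_subject_cell(self):
        df = records_frame([{"subject": 1, "condition": "CONG", "rt_ms": 205.0,
                             "success_initial": True}] * 10)
        table = bin_success(df)
        cell = table.subject_rates.iloc[0]
        assert cell.rate == 100.0 and cell.n_trials == 10

    def test_flat_half_success_has_no_delay(self, rng):
        df = simulate_records(rng, [0.5] * 13, 30, subjects=8)
        df2 = df.copy()
        df2["condition"] = "INCONG"
        table = bin_success(pd.concat([df, df2]))
        assert np.all(np.abs(table.group["mean"] - 50) < 15)
        d = estimate_delay(table, "CONG", "INCONG")
        assert d.delay_ms is None and d.qualifying_bin_a is None

    def test_empty_cells_absent_not_zero(self, rng):
        df = simulate_records(rng, [0.9] * 13, 5, subjects=3)
        df = df[(df.subject != 0) | (df.rt_ms >= 240)]  # subject 0 misses bins 0-1
        table = bin_success(df)
        sub0 = table.subject_rates[table.subject_rates.subject == 0]
        assert set(sub0["bin"]) == set(range(2, 13))
        g = table.group
        assert g[g.bin == 0]["n_subjects"].iloc[0] == 2

    def test_group_mean_invariant_to_ordering(self, rng):
        df = simulate_records(rng, np.linspace(0.5, 0.95, 13), 10, subjects=6)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = bin_success(df).group
        b = bin_success(shuffled).group
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_consistency_at_large_n(self, rng):
        """Recovered means converge to the generating curve (3 binomial SEs)."""
        p = np.linspace(0.55, 0.95, 13)
        n = 400
        df = simulate_records(rng, p, n, subjects=4)
        g = bin_success(df).group.sort_values("bin")
        se = 100 * np.sqrt(p * (1 - p) / (n * 4))
        assert np.all(np.abs(g["mean"].to_numpy() - 100 * p) < 3 * se)


def table_from_group(rows):
    group = pd.DataFrame(rows, columns=["condition", "bin", "bin_low", "bin_high",
                                        "mean", "ci_low", "ci_high", "n_subjects"])
    return BinnedSuccessTable(subject_rates=pd.DataFrame(
        columns=["subject", "condition", "bin", "bin_low", "bin_high", "rate",
                 "n_trials"]), group=group, edges=bin_edges(),
        value_col="success_initial")


def group_row(cond, b, mean, half):
    edges = bin_edges()
    return {"condition": cond, "bin": b, "bin_low": edges[b], "bin_high": edges[b + 1],
            "mean": mean, "ci_low": mean - half, "ci_high": mean + half,
            "n_subjects": 22}


class TestDelay:
    def test_censored_first_bin_gives_150(self):
        """a qualifies at [200,220) (left-censored), b at [340,360): 350-200."""
        rows = [group_row("A", b, 95.0 if b == 0 else 99.0, 2.0) for b in range(13)]
        rows += [group_row("B", b, 70.0, 2.0) for b in range(7)]
        rows += [group_row("B", b, 93.0, 4.0) for b in range(7, 13)]
        d = estimate_delay(table_from_group(rows), "A", "B")
        assert d.censored_a and d.qualifying_bin_a == 0 and d.qualifying_bin_b == 7
        assert d.delay_ms == 150.0 and d.uncertainty_ms == 10.0

    def test_same_bin_midpoints_give_zero(self):
        rows = [group_row("A", b, 80.0, 1.0) for b in range(13)]
        rows += [group_row("B", b, 80.0, 1.0) for b in range(13)]
        rows[5] = group_row("A", 5, 94.0, 2.0)
        rows[13 + 5] = group_row("B", 5, 94.0, 2.0)
        d = estimate_delay(table_from_group(rows), "A", "B")
        assert not d.censored_a and d.delay_ms == 0.0

    def test_never_qualifying_condition_flagged(self):
        rows = [group_row("A", b, 95.0, 1.0) for b in range(13)]
        rows += [group_row("B", b, 60.0, 1.0) for b in range(13)]
        d = estimate_delay(table_from_group(rows), "A", "B")
        assert d.delay_ms is None and d.qualifying_bin_b is None

    def test_missing_condition_raises(self):
        rows = [group_row("A", b, 95.0, 1.0) for b in range(13)]
        with pytest.raises(PreconditionError):
            estimate_delay(table_from_group(rows), "A", "B")


class TestContrast:
    def test_identical_conditions_no_differences(self, rng):
        df = simulate_records(rng, [0.7] * 13, 20, subjects=6)
        dup = df.copy()
        dup["condition"] = "INCONG"
        table = bin_success(pd.concat([df, dup]))
        out = binwise_contrast(table, "CONG", "INCONG")
        assert np.allclose(out["mean_diff"], 0.0)
        assert np.all(out["p_corrected"] == 1.0)

    def test_builtin_gap_recovered(self, rng):
        df_a = simulate_records(rng, [0.9] * 13, 60, subjects=10, condition="CONG")
        df_b = simulate_records(rng, [0.6] * 13, 60, subjects=10, condition="INCONG")
        table = bin_success(pd.concat([df_a, df_b]))
        out = binwise_contrast(table, "CONG", "INCONG")
        assert np.all(np.abs(out["mean_diff"] - 30.0) < 10)
        assert np.all(out["p_corrected"] < 0.05)


class TestGrouped:
    def test_rt_filter_and_grouping(self, rng):
        df = simulate_records(rng, [0.8] * 13, 10, subjects=4)
        df["configuration"] = np.where(df.index % 2 == 0, "CONF1", "CONF2")
        out = grouped_success(df, "configuration", conditions=("CONG",), rt_max=350)
        assert set(out["group"]) == {"CONF1", "CONF2"}
        # only RT < 350 trials can contribute
        kept = df[(df.rt_ms < 350) & (df.rt_ms >= 200)]
        assert out["n_trials"].sum() == len(kept)

    def test_unknown_grouping_rejected(self, rng):
        df = simulate_records(rng, [0.8] * 13, 2, subjects=2)
        with pytest.raises(PreconditionError):
            grouped_success(df, "colour")


class TestInitialVsFinal:
    def test_gain_is_difference_of_group_means(self, rng):
        rows = []
        for s in range(5):
            for b in range(13):
                for _ in range(20):
                    rt = 210 + 20 * b
                    init = rng.random() < 0.7
                    rows.append({"subject": s, "condition": "INCONG", "rt_ms": rt,
                                 "success_initial": init,
                                 "success_final": init or rng.random() < 0.1})
        df = records_frame(rows)
        out = initial_vs_final(df, "INCONG")
        assert len(out) == 13
        assert out["gain"].mean() == pytest.approx(
            (out["final"] - out["initial"]).mean())
        assert out["gain"].mean() > 0
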