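"""Paired tests, signed-rank statistics, and mixed-model fits."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from reachcost.errors import IncomparableModelsError, PreconditionError
from reachcost.stats import (MixedModelSpec, bonferroni, fit_mixed_logistic,
                             paired_test, select_by_aic, wilcoxon_vs_value)


class TestPairedTest:
    def test_identical_samples_degenerate(self):
        res = paired_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_raw == 1.0 and res.effect_size_d == 0.0

    def test_normal_shift_uses_t_branch(self, rng):
        x = rng.normal(10, 1, 30)
        res = paired_test(x + 2.0 + rng.normal(0, 0.5, 30), x)
        assert res.statistic_name == "t"
        assert res.p_raw < 1e-6 and res.effect_size_d > 1

    def test_skewed_differences_use_wilcoxon_branch(self, rng):
        x = rng.normal(0, 1, 60)
        y = x - rng.lognormal(0, 1.5, 60)  # heavily skewed positive differences
        res = paired_test(x, y)
        assert res.statistic_name == "W"
        assert res.p_raw < 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(PreconditionError):
            paired_test([1, 2, 3], [1, 2])


class TestWilcoxonVsValue:
    def test_uniformly_positive_differences_attain_bound(self):
        """22 proportions above 50% give W = 22*23/2 = 253."""
        x = 50.0 + np.linspace(1, 25, 22)
        res = wilcoxon_vs_value(x, 50.0)
        assert res.statistic_value == 253.0
        assert res.p_raw < 1e-4

    def test_uniformly_negative_differences_attain_zero(self):
        res = wilcoxon_vs_value(50.0 - np.linspace(1, 10, 10), 50.0)
        assert res.statistic_value == 0.0

    def test_symmetric_sample_near_half_bound(self, rng):
        x = 50.0 + np.concatenate([np.arange(1, 11), -np.arange(1, 11)])
        res = wilcoxon_vs_value(x, 50.0)
        n = len(x)
        assert res.statistic_value == pytest.approx(n * (n + 1) / 4, rel=0.05)
        assert res.p_raw > 0.5

    def test_all_equal_to_reference_degenerate(self):
        res = wilcoxon_vs_value(np.full(8, 50.0), 50.0)
        assert res.p_raw == 1.0

    def test_signed_rank_bounds_property(self, rng):
        """0 <= W <= n(n+1)/2 on random samples."""
        for _ in range(200):
            n = rng.integers(5, 30)
            x = rng.normal(50, 5, n)
            res = wilcoxon_vs_value(x, 50.0)
            assert 0 <= res.statistic_value <= n * (n + 1) / 2


class TestBonferroni:
    def test_monotone_and_capped(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.4, 5) == 1.0
        ps = [bonferroni(0.02, m) for m in range(1, 10)]
        assert ps == sorted(ps)


def _proportion_data(rng, n_subjects=12, effect=1.0):
    """Per-subject-per-cell binomial proportions with a condition effect."""
    rows = []
    for s in range(n_subjects):
        ability = rng.normal(0, 0.7)
        for cond, shift in [("A", 0.0), ("B", effect)]:
            for cell in range(4):
                eta = 0.5 + shift + ability
                p = 1 / (1 + np.exp(-eta))
                n = 40
                rows.append({"subject": s, "condition": cond, "cell": cell,
                             "n_trials": n, "prop": rng.binomial(n, p) / n})
    return pd.DataFrame(rows)


class TestMixedModels:
    def test_null_binomial_model_has_zero_marginal_r2(self, rng):
        data = _proportion_data(rng, effect=0.0)
        fit = fit_mixed_logistic(MixedModelSpec("prop ~ 1", family="binomial",
                                                weights="n_trials"), data)
        assert fit.marginal_r2 == pytest.approx(0.0, abs=1e-6)
        assert fit.conditional_r2 >= fit.marginal_r2

    def test_condition_effect_detected(self, rng):
        data = _proportion_data(rng, effect=1.2)
        fit = fit_mixed_logistic(MixedModelSpec("prop ~ condition", family="binomial",
                                                weights="n_trials"), data)
        assert fit.converged
        om = fit.omnibus.set_index("term")
        assert om.loc["condition", "p"] < 1e-4
        assert fit.conditional_r2 >= fit.marginal_r2 > 0

    def test_gaussian_family_fits_and_orders_r2(self, rng):
        data = _proportion_data(rng, effect=0.8)
        data["rate"] = 100 * data["prop"]
        fit = fit_mixed_logistic(MixedModelSpec("rate ~ condition", family="gaussian"),
                                 data)
        assert fit.conditional_r2 >= fit.marginal_r2 >= 0
        assert fit.omnibus.set_index("term").loc["condition", "p"] < 0.01

    def test_aic_selection_prefers_true_model(self, rng):
        data = _proportion_data(rng, effect=1.2)
        null = fit_mixed_logistic(MixedModelSpec("prop ~ 1", family="binomial",
                                                 weights="n_trials"), data)
        full = fit_mixed_logistic(MixedModelSpec("prop ~ condition", family="binomial",
                                                 weights="n_trials"), data)
        assert select_by_aic([null, full]) is full

    def test_aic_tie_breaks_on_parameters(self):
        a = fit_a = _FakeFit("y", aic=-100.0, n_params=7, nobs=50)
        b = _FakeFit("y", aic=-100.0, n_params=5, nobs=50)
        assert select_by_aic([a, b]) is b
        assert select_by_aic([_FakeFit("y", -120.0, 9, 50), fit_a]) .aic == -120.0

    def test_mixed_responses_incomparable(self):
        with pytest.raises(IncomparableModelsError):
            select_by_aic([_FakeFit("y", -10, 3, 50), _FakeFit("z", -20, 3, 50)])

    def test_binomial_fit_matches_lme4_oracle(self, rng, tmp_path):
        """Cross-check the quadrature GLMM against lme4::glmer on a tiny set."""
        data = _proportion_data(rng, n_subjects=10, effect=1.0)
        fit = fit_mixed_logistic(MixedModelSpec("prop ~ condition", family="binomial",
                                                weights="n_trials"), data)
        csv = tmp_path / "d.csv"
        data.assign(succ=lambda d: (d.prop * d.n_trials).round()).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(cbind(succ, n_trials - succ) ~ condition + (1 | subject),
                       data = d, family = binomial, nAGQ = 25)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), AIC(m), sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.split()]
        assert fit.params.iloc[0] == pytest.approx(ref[0], abs=0.02)
        assert fit.params.iloc[1] == pytest.approx(ref[1], abs=0.02)
        assert fit.sigma_subject == pytest.approx(ref[2], rel=0.05, abs=0.02)
        assert fit.aic == pytest.approx(ref[3], abs=0.5)


class _FakeFit:
    def __init__(self, response, aic, n_params, nobs):
        self.response = response
        self.aic = aic
        self.n_params = n_params
        self.nobs = nobs
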