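"""Statistical layer: normality-gated paired tests, one-sample signed-rank
tests against chance, Bonferroni correction, Cohen's d, and mixed-effects
models with AIC selection.

Pairwise comparisons use a paired t test when the Shapiro-Wilk test does not
reject normality of the differences (p >= 0.05) and a Wilcoxon signed-rank
test otherwise.  The reported signed-rank statistic W is the sum of positive
ranks, so 22 uniformly positive differences give W = 22*23/2 = 253.

Mixed models always include a subject random term.  The gaussian family wraps
statsmodels' linear mixed model (fitted by ML so AICs are comparable); the
binomial family is a random-intercept logistic mixed model whose likelihood is
integrated over the subject effect by Gauss-Hermite quadrature.  Marginal and
conditional R-squared follow the Nakagawa variance-partition convention (on
the latent scale, with pi^2/3 as the binomial residual variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special
from scipy import stats as sps

from .errors import IncomparableModelsError, PreconditionError

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic_name: str  # "t" or "W"
    statistic_value: float
    df: Optional[float]
    p_raw: float
    p_corrected: float
    correction: str  # "none" or "bonferroni"
    effect_size_d: float
    n: int

    def corrected(self, m: int) -> "TestResult":
        """Bonferroni-correct this result for *m* comparisons."""
        return TestResult(self.statistic_name, self.statistic_value, self.df,
                          self.p_raw, bonferroni(self.p_raw, m), "bonferroni",
                          self.effect_size_d, self.n)


def bonferroni(p: float, m: int) -> float:
    """min(1, m*p) for m comparisons."""
    if m < 1:
        raise PreconditionError("m must be >= 1")
    return min(1.0, m * p)


def cohens_d_paired(diff: np.ndarray) -> float:
    """Paired Cohen's d: mean of differences over their SD."""
    sd = np.std(diff, ddof=1)
    return float(np.mean(diff) / sd) if sd > 0 else 0.0


def _signed_rank_statistic(diff: np.ndarray) -> float:
    """Sum of ranks of positive differences (zeros dropped, ties mid-ranked)."""
    diff = diff[diff != 0]
    ranks = sps.rankdata(np.abs(diff))
    return float(ranks[diff > 0].sum())


def paired_test(x: Sequence[float], y: Sequence[float],
                alpha_normality: float = SHAPIRO_ALPHA) -> TestResult:
    """Paired comparison with a Shapiro-Wilk normality gate.

    Differences passing the gate (Shapiro-Wilk p >= 0.05) are tested with a
    paired t test; otherwise a Wilcoxon signed-rank test is used.  All-zero
    differences are degenerate and return p = 1, d = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise PreconditionError("x and y must be equal-length 1-D samples")
    if len(x) < 3:
        raise PreconditionError("need at least 3 pairs")
    diff = x - y
    if np.all(diff == 0):
        return TestResult("t", 0.0, float(len(x) - 1), 1.0, 1.0, "none", 0.0, len(x))
    sw_p = sps.shapiro(diff).pvalue
    d = cohens_d_paired(diff)
    if sw_p >= alpha_normality:
        res = sps.ttest_rel(x, y)
        return TestResult("t", float(res.statistic), float(len(x) - 1),
                          float(res.pvalue), float(res.pvalue), "none", d, len(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact/approx switching for small n
        p = float(sps.wilcoxon(diff[diff != 0]).pvalue)
    return TestResult("W", _signed_rank_statistic(diff), None, p, p, "none", d, len(x))


def wilcoxon_vs_value(x: Sequence[float], mu: float = 50.0) -> TestResult:
    """One-sample Wilcoxon signed-rank test of *x* against a reference value.

    Used for LC-target choice proportions against chance (50%).  The statistic
    is the positive-rank sum W, bounded by n(n+1)/2 and attaining that bound
    when every observation exceeds *mu*.
    """
    x = np.asarray(x, float)
    if x.ndim != 1 or len(x) < 5:
        raise PreconditionError("need a 1-D sample of at least 5 values")
    diff = x - mu
    if np.all(diff == 0):
        return TestResult("W", 0.0, None, 1.0, 1.0, "none", 0.0, len(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps.wilcoxon(diff[diff != 0]).pvalue)
    return TestResult("W", _signed_rank_statistic(diff), None, p, p, "none",
                      cohens_d_paired(diff), len(x))


# ---------------------------------------------------------------------------
# Mixed-effects models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixedModelSpec:
    """Declarative model description.

    ``formula`` is a patsy fixed-effects formula (response on the left); the
    subject grouping column provides the mandatory random intercept, and
    ``re_formula`` adds random slopes (gaussian family only).  For the binomial
    family the response column holds per-cell proportions in [0, 1] and
    ``weights`` names the per-cell trial-count column.
    """

    formula: str
    family: str = "gaussian"  # or "binomial"
    groups: str = "subject"
    re_formula: Optional[str] = None
    weights: Optional[str] = None

    @property
    def response(self) -> str:
        return self.formula.split("~")[0].strip()


@dataclass
class MixedModelFit:
    spec: MixedModelSpec
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    aic: float
    bic: float
    n_params: int
    nobs: int
    sigma_subject: float
    marginal_r2: float
    conditional_r2: float
    omnibus: pd.DataFrame  # term, wald_chi2, df, p
    converged: bool
    notes: list[str] = field(default_factory=list)

    @property
    def response(self) -> str:
        return self.spec.response


_LOGIT_RESID_VAR = np.pi ** 2 / 3


def _term_wald_tests(design_info, params: np.ndarray, cov: np.ndarray) -> pd.DataFrame:
    """Wald chi-square omnibus test for each non-intercept fixed term."""
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        b = params[sl]
        vb = cov[sl, sl]
        try:
            stat = float(b @ np.linalg.solve(vb, b))
        except np.linalg.LinAlgError:
            stat = np.nan
        df = len(b)
        rows.append({"term": term, "wald_chi2": stat, "df": df,
                     "p": float(sps.chi2.sf(stat, df)) if np.isfinite(stat) else np.nan})
    return pd.DataFrame(rows, columns=["term", "wald_chi2", "df", "p"])


def _fit_gaussian(spec: MixedModelSpec, data: pd.DataFrame) -> MixedModelFit:
    import statsmodels.formula.api as smf

    model = smf.mixedlm(spec.formula, data, groups=data[spec.groups],
                        re_formula=spec.re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    k_fe = model.k_fe
    # parameters: fixed effects + unique random-covariance entries + residual
    n_params = len(res.params) + 1
    aic = 2 * n_params - 2 * res.llf
    bic = n_params * np.log(model.nobs) - 2 * res.llf

    X = model.exog
    beta = res.fe_params.to_numpy()
    var_f = float(np.var(X @ beta))
    Z = model.exog_re if model.exog_re is not None else np.ones((model.nobs, 1))
    cov_re = np.atleast_2d(res.cov_re.to_numpy())
    var_re = float(np.mean(np.einsum("ij,jk,ik->i", Z, cov_re, Z)))
    var_resid = float(res.scale)
    total = var_f + var_re + var_resid
    design_info = model.data.design_info
    cov_fe = res.cov_params().to_numpy()[:k_fe, :k_fe]
    fit = MixedModelFit(
        spec=spec, params=res.params, cov_params=res.cov_params(),
        llf=float(res.llf), aic=float(aic), bic=float(bic), n_params=n_params,
        nobs=int(model.nobs), sigma_subject=float(np.sqrt(max(cov_re[0, 0], 0.0))),
        marginal_r2=var_f / total, conditional_r2=(var_f + var_re) / total,
        omnibus=_term_wald_tests(design_info, beta, cov_fe),
        converged=bool(res.converged))
    return fit


def _posterior_modes(eta: np.ndarray, succ: np.ndarray, n: np.ndarray,
                     groups: np.ndarray, n_groups: int, sigma: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject mode and curvature scale of the random-intercept posterior."""
    b = np.zeros(n_groups)
    inv_var = 1.0 / sigma ** 2
    for _ in range(50):
        pi = special.expit(eta + b[groups])
        score = np.bincount(groups, succ - n * pi, minlength=n_groups) - b * inv_var
        info = np.bincount(groups, n * pi * (1 - pi), minlength=n_groups) + inv_var
        step = np.clip(score / info, -2.0, 2.0)
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    pi = special.expit(eta + b[groups])
    info = np.bincount(groups, n * pi * (1 - pi), minlength=n_groups) + inv_var
    return b, 1.0 / np.sqrt(info)


def _binomial_nll(theta: np.ndarray, X: np.ndarray, succ: np.ndarray,
                  n: np.ndarray, groups: np.ndarray, gh_x: np.ndarray,
                  gh_logw: np.ndarray) -> float:
    """Negative marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    Nodes are recentred and rescaled at each subject's posterior mode, as in
    lme4's nAGQ > 1 fits; plain quadrature undersamples the sharply peaked
    integrand once a subject contributes hundreds of trials.
    """
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta  # (nobs,)
    n_groups = int(groups.max()) + 1
    mode, tau = _posterior_modes(eta, succ, n, groups, n_groups, sigma)
    # adaptive nodes: (groups, nodes)
    b_nodes = mode[:, None] + np.sqrt(2.0) * tau[:, None] * gh_x[None, :]
    z = eta[:, None] + b_nodes[groups]  # (nobs, nodes)
    logp = -np.logaddexp(0.0, -z)
    log1mp = -np.logaddexp(0.0, z)
    ll_obs = succ[:, None] * logp + (n - succ)[:, None] * log1mp
    ll_grp = np.zeros((n_groups, len(gh_x)))
    np.add.at(ll_grp, groups, ll_obs)
    log_prior = (-0.5 * np.log(2 * np.pi) - np.log(sigma)
                 - 0.5 * (b_nodes / sigma) ** 2)
    # int exp(g(b)) db ~ sqrt(2)*tau * sum_q w_q e^{x_q^2} exp(g(b_q))
    log_w = gh_logw[None, :] + 0.5 * np.log(np.pi)  # raw log GH weights
    joint = ll_grp + log_prior + log_w + gh_x[None, :] ** 2
    logz = special.logsumexp(joint, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
    return -float(logz.sum())


def _fit_binomial(spec: MixedModelSpec, data: pd.DataFrame,
                  gh_points: int = 31) -> MixedModelFit:
    import statsmodels.api as sm
    from statsmodels.tools.numdiff import approx_hess

    notes = []
    if spec.re_formula not in (None, "1", "~1"):
        notes.append("random slopes unsupported for the binomial family; "
                     "fitted with a random intercept only")
    if spec.weights is None:
        raise PreconditionError("binomial family needs a trial-count weights column")
    y, X = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    prop = y.to_numpy().ravel()
    if np.any((prop < 0) | (prop > 1)):
        raise PreconditionError("binomial response must be a proportion in [0, 1]")
    n = data[spec.weights].to_numpy(float)
    succ = np.round(prop * n)
    groups, _ = pd.factorize(data[spec.groups], sort=True)
    Xm = X.to_numpy()

    # start from an unconditional GLM fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(np.column_stack([succ, n - succ]), Xm,
                     family=sm.families.Binomial()).fit()
    theta0 = np.append(glm.params, np.log(0.5))
    gh_x, gh_w = np.polynomial.hermite.hermgauss(gh_points)
    gh_logw = np.log(gh_w) - 0.5 * np.log(np.pi)
    args = (Xm, succ, n, groups, gh_x, gh_logw)

    bounds = [(None, None)] * (len(theta0) - 1) + [(-6.0, 3.0)]
    res = optimize.minimize(_binomial_nll, theta0, args=args, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    converged = bool(res.success)
    if not converged:
        notes.append(f"optimizer: {res.message}")
    theta = res.x
    # log-likelihood relative to the saturated model (lme4/jamovi convention;
    # the binomial coefficients cancel, and AIC differences are unaffected)
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = succ / n
        sat = (np.where(succ > 0, succ * np.log(phat), 0.0)
               + np.where(n - succ > 0, (n - succ) * np.log1p(-phat), 0.0))
    llf = -res.fun - float(sat.sum())
    n_params = len(theta)
    nobs = len(prop)
    aic = 2 * n_params - 2 * llf
    bic = n_params * np.log(nobs) - 2 * llf

    hess = approx_hess(theta, _binomial_nll, args=args)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((n_params, n_params), np.nan)
        notes.append("singular Hessian; no covariance available")
    names = list(X.columns) + ["log_sigma_subject"]
    beta = theta[:-1]
    sigma = float(np.exp(theta[-1]))
    var_f = float(np.var(Xm @ beta))
    total = var_f + sigma ** 2 + _LOGIT_RESID_VAR
    fit = MixedModelFit(
        spec=spec, params=pd.Series(theta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        llf=float(llf), aic=float(aic), bic=float(bic), n_params=n_params,
        nobs=nobs, sigma_subject=sigma,
        marginal_r2=var_f / total, conditional_r2=(var_f + sigma ** 2) / total,
        omnibus=_term_wald_tests(X.design_info, beta, cov[:-1, :-1]),
        converged=converged, notes=notes)
    return fit


def fit_mixed_logistic(spec: MixedModelSpec, data: pd.DataFrame) -> MixedModelFit:
    """Fit a mixed-effects model with a mandatory subject random term.

    Non-convergence is reported on the returned fit (``converged`` flag and
    ``notes``), never silently dropped.
    """
    if spec.groups not in data.columns:
        raise PreconditionError(f"grouping column {spec.groups!r} missing")
    if spec.family == "gaussian":
        return _fit_gaussian(spec, data)
    if spec.family == "binomial":
        return _fit_binomial(spec, data)
    raise PreconditionError(f"unknown family {spec.family!r}")


def select_by_aic(fits: Sequence[MixedModelFit]) -> MixedModelFit:
    """The lowest-AIC fit among candidates on the same response and data size.

    Ties are broken in favour of fewer parameters.
    """
    if len(fits) < 2:
        raise PreconditionError("need at least two candidate fits")
    responses = {f.response for f in fits}
    if len(responses) > 1:
        raise IncomparableModelsError(f"AIC not comparable across responses {responses}")
    if len({f.nobs for f in fits}) > 1:
        raise IncomparableModelsError("AIC not comparable across different data sizes")
    return min(fits, key=lambda f: (f.aic, f.n_params))
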