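"""Hierarchical mixed-model meta-regression of log response ratios.

LRRs are modelled with Gaussian linear mixed models carrying the nested
random-intercept structure of the synthesis design: study, site within
study and — at the local and turnover scales, where one row per block
exists — block within site.  Fixed effects are drawn from the manipulation
magnitude (delta_P), background climate (MAP, or PET as a substitute),
experiment duration and the delta_P x climate interaction; covariates are
standardised by centring and dividing by two standard deviations, which
puts continuous slopes on a scale comparable to binary contrasts.

Model selection compares maximum-likelihood fits by AICc over a nested
candidate ladder that respects marginality; the selected specification is
refit by REML for reported estimates.  Uncertainty is quantified by a
parametric bootstrap (simulate from the fitted model, refit, take
percentile intervals): an effect is called significant when its 95%
interval excludes zero.  Degrees-of-freedom based p-values are deliberately
not computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize
from scipy import linalg as sla
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "standardize_covariates",
    "back_transform",
    "prepare_effects",
    "fit_lmm",
    "aicc",
    "candidate_set",
    "select_model",
    "bootstrap_ci",
    "conditional_r2",
    "quadratic_test",
    "direction_interaction_test",
    "fit_marginal_lmm",
]

_SCALED_SUFFIX = "_s"


def standardize_covariates(table: pd.DataFrame, variables: list[str]):
    """Centre each variable and divide by twice its standard deviation.

    Returns the table with new ``<var>_s`` columns plus a scaling record
    {var: (mean, sd)} for back-transformation.  A constant variable is an
    error: its scaled version would be undefined.
    """
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for var in variables:
        x = pd.to_numeric(out[var])
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"covariate {var!r} is constant; cannot standardise")
        out[var + _SCALED_SUFFIX] = (x - mu) / (2.0 * sd)
        scaling[var] = (mu, sd)
    return out, scaling


def back_transform(values, var: str, scaling: dict):
    """Invert the 2-SD standardisation for one variable."""
    mu, sd = scaling[var]
    return np.asarray(values, dtype=float) * 2.0 * sd + mu


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: fixed-effect terms plus the random structure.

    ``fixed_terms`` uses formula syntax on the scaled covariate columns
    (e.g. ``("delta_P_s", "MAP_s", "delta_P_s:MAP_s")``); the empty tuple is
    the intercept-only model.  ``scale`` selects the random structure:
    block-in-site-in-study for local/turnover rows, site-in-study for the
    one-row-per-experiment site scale.
    """

    fixed_terms: tuple[str, ...] = ()
    scale: str = "local"
    response: str = "lrr"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"{self.response} ~ {rhs}"

    @property
    def name(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "1"

    def satisfies_marginality(self) -> bool:
        terms = set(self.fixed_terms)
        for t in terms:
            if ":" in t:
                if not all(p in terms for p in t.split(":")):
                    return False
            if t.startswith("I(") and "** 2" in t:
                base = t[2:].split("**")[0].strip()
                if base not in terms:
                    return False
        return True


@dataclass
class MixedModelFit:
    spec: ModelSpec
    coefficients: dict
    coef_se: dict
    coef_ci: dict = field(default_factory=dict)
    variance_components: dict = field(default_factory=dict)
    residual_variance: float = np.nan
    log_likelihood: float = np.nan
    n_obs: int = 0
    k_params: int = 0
    aic: float = np.nan
    aicc: float = np.nan
    marginal_r2: float = np.nan
    conditional_r2: float = np.nan
    converged: bool = False
    method: str = "ML"
    seed: int | None = None
    weights_column: str | None = None
    result: object | None = None  # statsmodels wrapper, for bootstrap reuse

    def significant(self, term: str) -> bool:
        lo, hi = self.coef_ci[term]
        return lo > 0 or hi < 0


def prepare_effects(
    effects: pd.DataFrame,
    metric: str,
    scale: str,
    climate: str = "MAP",
    standardize: bool = True,
):
    """Subset one response (metric x scale) and standardise its covariates.

    Builds globally unique site/block grouping keys and returns
    (table, scaling record).  Rows with any missing covariate are dropped so
    every candidate model sees the same rows.
    """
    df = effects[(effects["metric"] == metric) & (effects["scale"] == scale)].copy()
    covs = ["delta_P", climate, "duration"]
    need = [c for c in covs if c in df.columns]
    df = df.dropna(subset=need + ["lrr"])
    if standardize:
        df, scaling = standardize_covariates(df, need)
    else:
        scaling = {}
    if "site_id" not in df.columns:
        df["site_id"] = df["experiment_id"]
    df["site_uid"] = df["study_id"].astype(str) + "/" + df["site_id"].astype(str)
    if scale in ("local", "turnover") and "block_id" in df.columns:
        df["block_uid"] = df["site_uid"] + "/" + df["block_id"].astype(str)
    return df.reset_index(drop=True), scaling


def _vc_formula(scale: str, df: pd.DataFrame) -> dict:
    """Random structure for a scale; drops unidentifiable components.

    A block variance component with a single row per block level is aliased
    with the residual variance (one observation per level), so it is only
    included when at least one block contributes multiple rows — e.g. when
    several treatments share a control block.
    """
    vc = {"site": "0 + C(site_uid)"}
    if scale in ("local", "turnover") and "block_uid" in df.columns:
        if df.groupby("block_uid").size().max() > 1:
            vc["block"] = "0 + C(block_uid)"
    return vc


def fit_lmm(df: pd.DataFrame, spec: ModelSpec, reml: bool = False) -> MixedModelFit:
    """Fit one mixed model; ML by default (for AICc), REML on request.

    Random structure: random intercept per study (grouping factor) plus
    variance components for site-in-study and, at local/turnover scales,
    block-in-site.  Non-convergence is flagged on the returned fit, never
    silently dropped.
    """
    vc = _vc_formula(spec.scale, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM.from_formula(
            spec.formula,
            data=df,
            groups=df["study_id"],
            re_formula="1",
            vc_formula=vc,
        )
        res, converged = None, False
        for method in ("lbfgs", "powell", "cg"):
            try:
                res = model.fit(reml=reml, method=method, maxiter=500)
                converged = bool(res.converged)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if converged:
                break
        bse_fe = None
        if res is not None:
            bse_fe = res.bse_fe  # computed here so singular-fit noise stays suppressed

    if res is None:
        return MixedModelFit(
            spec=spec, coefficients={}, coef_se={}, converged=False,
            method="REML" if reml else "ML", n_obs=len(df),
        )

    fe = res.fe_params
    vcomp = {}
    vc_names = list(model.exog_vc.names) if model.exog_vc is not None else []
    for name, var in zip(vc_names, np.atleast_1d(res.vcomp)):
        vcomp[name] = float(var)
    var_study = float(np.asarray(res.cov_re)[0, 0])
    variance_components = {"study": var_study, **vcomp}
    resid_var = float(res.scale)

    k = len(fe) + len(variance_components) + 1  # + residual variance
    n = len(df)
    llf = float(res.llf)
    fit = MixedModelFit(
        spec=spec,
        coefficients={k_: float(v) for k_, v in fe.items()},
        coef_se={k_: float(v) for k_, v in bse_fe.items()},
        variance_components=variance_components,
        residual_variance=resid_var,
        log_likelihood=llf,
        n_obs=n,
        k_params=k,
        converged=converged,
        method="REML" if reml else "ML",
        result=res,
    )
    fit.aic = -2.0 * llf + 2.0 * k
    fit.aicc = aicc(llf, k, n)
    fit.marginal_r2, fit.conditional_r2 = conditional_r2(fit)
    return fit


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: AIC + 2k(k+1)/(n-k-1).

    k counts all estimated parameters: fixed effects, every random-effect
    variance and the residual variance.
    """
    if n <= k + 1:
        return float("inf")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def conditional_r2(fit: MixedModelFit) -> tuple[float, float]:
    """Variance-partition R2 for Gaussian mixed models.

    marginal = var(fixed predictor) / total; conditional adds the summed
    random-intercept variances to the numerator; total includes the
    residual variance.
    """
    res = fit.result
    if res is None:
        return np.nan, np.nan
    X = res.model.exog
    beta = np.asarray(res.fe_params)
    var_f = float(np.var(X @ beta))
    var_re = float(sum(fit.variance_components.values()))
    total = var_f + var_re + fit.residual_variance
    if total <= 0:
        return np.nan, np.nan
    return var_f / total, (var_f + var_re) / total


def candidate_set(
    climate: str = "MAP",
    scale: str = "local",
    include_duration: bool = True,
    quadratic: bool = False,
    direction_interaction: bool = False,
) -> list[ModelSpec]:
    """Nested ladder of candidate fixed-effect structures.

    {1} subset {dP} subset {dP, climate} subset {dP, climate, dP x climate}
    subset {..., duration}; optional robustness variants append the
    quadratic dP term or the dP x direction interaction to each
    dP-containing spec.  All specs satisfy marginality by construction.
    """
    dp = "delta_P_s"
    cl = climate + _SCALED_SUFFIX
    ladders: list[tuple[str, ...]] = [
        (),
        (dp,),
        (dp, cl),
        (dp, cl, f"{dp}:{cl}"),
    ]
    if include_duration:
        ladders.append((dp, cl, f"{dp}:{cl}", "duration_s"))
    specs = [ModelSpec(fixed_terms=t, scale=scale) for t in ladders]
    if quadratic:
        specs += [
            ModelSpec(fixed_terms=t + (f"I({dp} ** 2)",), scale=scale)
            for t in ladders
            if dp in t
        ]
    if direction_interaction:
        specs += [
            ModelSpec(fixed_terms=t + ("direction", f"{dp}:direction"), scale=scale)
            for t in ladders
            if dp in t
        ]
    assert all(s.satisfies_marginality() for s in specs)
    return specs


def select_model(df: pd.DataFrame, candidates: list[ModelSpec]):
    """Rank candidates by AICc of ML fits; REML-refit the winner.

    All candidates are fit on the identical row set (callers drop rows with
    missing covariates in :func:`prepare_effects`).  Non-converged
    candidates are excluded and reported in the ranking table.  Ties in
    AICc go to the model with fewer parameters.
    """
    records = []
    fits = {}
    for spec in candidates:
        fit = fit_lmm(df, spec, reml=False)
        fits[spec.name] = fit
        records.append(
            {
                "model": spec.name,
                "k": fit.k_params,
                "aicc": fit.aicc,
                "log_lik": fit.log_likelihood,
                "converged": fit.converged,
            }
        )
    rank = pd.DataFrame(records)
    ok = rank[rank["converged"]].sort_values(["aicc", "k"], kind="stable")
    if ok.empty:
        raise RuntimeError("no candidate model converged")
    rank = pd.concat([ok, rank[~rank["converged"]]], ignore_index=True)
    rank["delta_aicc"] = rank["aicc"] - ok["aicc"].iloc[0]
    best_name = ok["model"].iloc[0]
    best_spec = next(s for s in candidates if s.name == best_name)
    best_fit = fit_lmm(df, best_spec, reml=True)
    best_fit.aicc = fits[best_name].aicc  # comparison value stays ML-based
    best_fit.aic = fits[best_name].aic
    return rank, best_fit


def _simulate_response(df: pd.DataFrame, fit: MixedModelFit, rng: np.random.Generator):
    """Draw a response vector from the fitted model's estimated distribution."""
    res = fit.result
    mu = res.model.exog @ np.asarray(res.fe_params)
    y = mu.copy()
    sd_study = np.sqrt(max(fit.variance_components.get("study", 0.0), 0.0))
    groups = {"study": df["study_id"].to_numpy()}
    if "site" in fit.variance_components:
        groups["site"] = df["site_uid"].to_numpy()
    if "block" in fit.variance_components:
        groups["block"] = df["block_uid"].to_numpy()
    for name, labels in groups.items():
        sd = np.sqrt(max(fit.variance_components.get(name, 0.0), 0.0))
        if sd == 0:
            continue
        levels, inv = np.unique(labels, return_inverse=True)
        y = y + rng.normal(0.0, sd, size=len(levels))[inv]
    y = y + rng.normal(0.0, np.sqrt(max(fit.residual_variance, 0.0)), size=len(df))
    return y


def bootstrap_ci(
    df: pd.DataFrame,
    spec: ModelSpec,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    fit: MixedModelFit | None = None,
    alpha: float = 0.05,
    reml: bool = True,
):
    """Parametric-bootstrap percentile CIs for the fixed effects.

    Simulates the response from the fitted model (respecting the nested
    random structure), refits, and takes the alpha/2 and 1 - alpha/2
    percentiles of each coefficient.  Failed refits are skipped; more than
    10% failures raises a warning on the returned fit.
    """
    rng = np.random.default_rng() if rng is None else rng
    if fit is None:
        fit = fit_lmm(df, spec, reml=reml)
    if not fit.converged:
        raise RuntimeError("cannot bootstrap a non-converged fit")
    names = list(fit.coefficients)
    draws = np.full((n_iter, len(names)), np.nan)
    failures = 0
    model0 = fit.result.model  # design matrices are reused across refits
    groups = df["study_id"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(n_iter):
            y = _simulate_response(df, fit, rng)
            bmodel = MixedLM(
                y, model0.exog, groups=groups,
                exog_re=model0.exog_re, exog_vc=model0.exog_vc,
            )
            try:
                bres = bmodel.fit(reml=reml, method="lbfgs", maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                try:
                    bres = bmodel.fit(reml=reml, method="powell", maxiter=500)
                except (np.linalg.LinAlgError, ValueError):
                    failures += 1
                    continue
            params = np.asarray(bres.fe_params)
            # refits at the variance boundary are legitimate draws; only
            # numerically broken refits are discarded
            if np.all(np.isfinite(params)):
                draws[b] = params
            else:
                failures += 1
    if failures > 0.1 * n_iter:
        warnings.warn(
            f"{failures}/{n_iter} bootstrap refits failed to converge", stacklevel=2
        )
    lo = np.nanpercentile(draws, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(draws, 100 * (1 - alpha / 2), axis=0)
    fit.coef_ci = {k: (float(l), float(h)) for k, l, h in zip(names, lo, hi)}
    return fit.coef_ci, draws


def _compare(
    df: pd.DataFrame, base: ModelSpec, extended: ModelSpec, margin: float = 2.0
) -> dict:
    """Pairwise AICc comparison with a parsimony margin.

    The extended model wins only when it improves AICc by more than
    ``margin`` (default 2, the conventional threshold below which two
    models have comparable support); otherwise the simpler model is
    retained.
    """
    fit_base = fit_lmm(df, base, reml=False)
    fit_ext = fit_lmm(df, extended, reml=False)
    delta = fit_ext.aicc - fit_base.aicc
    winner = "extended" if delta < -margin else "base"
    return {
        "base": base.name,
        "extended": extended.name,
        "aicc_base": fit_base.aicc,
        "aicc_extended": fit_ext.aicc,
        "delta_aicc": abs(delta),
        "winner": winner,
        "fit_base": fit_base,
        "fit_extended": fit_ext,
    }


def quadratic_test(df: pd.DataFrame, base_spec: ModelSpec) -> dict:
    """AICc comparison of the linear delta_P model against adding delta_P^2."""
    if "delta_P_s" not in base_spec.fixed_terms:
        raise ValueError("base spec must contain the linear delta_P term")
    ext = replace(
        base_spec, fixed_terms=base_spec.fixed_terms + ("I(delta_P_s ** 2)",)
    )
    return _compare(df, base_spec, ext)


def direction_interaction_test(df: pd.DataFrame, base_spec: ModelSpec) -> dict:
    """Test for different delta_P slopes under increase vs decrease treatments."""
    if df["direction"].nunique() < 2:
        raise ValueError("both manipulation directions must be present")
    ext = replace(
        base_spec,
        fixed_terms=base_spec.fixed_terms + ("direction", "delta_P_s:direction"),
    )
    rep = _compare(df, base_spec, ext)
    fe = rep["fit_extended"].coefficients
    slope_dec = fe.get("delta_P_s", np.nan)
    inter = next((v for k, v in fe.items() if k.startswith("delta_P_s:direction")), 0.0)
    rep["slope_decrease"] = slope_dec
    rep["slope_increase"] = slope_dec + inter
    rep["slope_difference"] = inter
    se = rep["fit_extended"].coef_se
    rep["slope_difference_se"] = next(
        (v for k, v in se.items() if k.startswith("delta_P_s:direction")), np.nan
    )
    return rep


# ---------------------------------------------------------------------------
# Direct marginal-likelihood fitter (supports per-row residual weights)
# ---------------------------------------------------------------------------

def fit_marginal_lmm(
    y: np.ndarray,
    X: np.ndarray,
    group_labels: list[np.ndarray],
    weights: np.ndarray | None = None,
    reml: bool = False,
):
    """ML/REML fit of a random-intercept LMM by direct marginal likelihood.

    V = sum_k sigma_k^2 Z_k Z_k' + sigma_e^2 diag(1/w); beta is profiled
    out by GLS at each variance evaluation.  Used for the sqrt(n)-weighted
    sensitivity refit, where each row's residual precision is proportional
    to its weight.  Returns (beta, variance dict, llf, converged).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    Zs = []
    for labels in group_labels:
        levels, inv = np.unique(np.asarray(labels), return_inverse=True)
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), inv] = 1.0
        Zs.append(Z)
    n_vc = len(Zs)
    Winv = np.diag(1.0 / w)

    def neg_ll(log_sds):
        sds = np.exp(log_sds)
        V = (sds[-1] ** 2) * Winv
        for k in range(n_vc):
            V = V + (sds[k] ** 2) * (Zs[k] @ Zs[k].T)
        try:
            c, low = sla.cho_factor(V, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_X = sla.cho_solve((c, low), X, check_finite=False)
        Vi_y = sla.cho_solve((c, low), y, check_finite=False)
        XtViX = X.T @ Vi_X
        try:
            beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        except np.linalg.LinAlgError:
            return 1e12
        r = y - X @ beta
        Vi_r = sla.cho_solve((c, low), r, check_finite=False)
        ll = -0.5 * (logdet + r @ Vi_r + n * np.log(2 * np.pi))
        if reml:
            sign, ld2 = np.linalg.slogdet(XtViX)
            ll -= 0.5 * ld2
        return -ll

    x0 = np.full(n_vc + 1, np.log(max(np.std(y), 1e-3) * 0.5))
    opt = scipy.optimize.minimize(
        neg_ll, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000},
    )
    sds = np.exp(opt.x)
    # recover beta at the optimum
    V = (sds[-1] ** 2) * Winv
    for k in range(n_vc):
        V = V + (sds[k] ** 2) * (Zs[k] @ Zs[k].T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    variances = {f"group{k}": float(sds[k] ** 2) for k in range(n_vc)}
    variances["residual"] = float(sds[-1] ** 2)
    return beta, variances, -float(opt.fun), bool(opt.success)
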