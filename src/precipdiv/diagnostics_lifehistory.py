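"""Life-history analyses and scale-dependence diagnostics.

Two questions about the dominant species of each site: (1) is the
probability that the dominant is monocarpic (an annual or biennial, coded
1) rather than polycarpic (perennial, coded 0) related to background
climate?  — answered with a maximum-likelihood random-intercept logistic
regression (study as the random term) and a likelihood-ratio chi-square;
(2) do communities dominated by monocarps respond differently to the
manipulations? — answered with mixed models of the LRRs with life history
as a two-level fixed factor and study as the random term.

The scale-dependence diagnostics screen the synthesis for study-level
artefacts: correlations of the per-study mean and variance of each effect
size with sample size and plot size, correlations of the moderators with
those design variables, leave-one-out refits flagging studies whose
removal flips a fitted slope's sign, and a sqrt(sample-size)-weighted
sensitivity refit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import roots_hermite
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .inference import ModelSpec, fit_lmm, fit_marginal_lmm

__all__ = [
    "DominanceRecord",
    "dominant_species",
    "MixedLogisticFit",
    "fit_lifehistory_model",
    "lifehistory_group_test",
    "spake_codependence",
    "weighted_refit",
]

logger = logging.getLogger(__name__)


@dataclass
class DominanceRecord:
    site_id: str
    dominant_species: str
    basis: float  # mean control abundance per plot
    life_history: str | None = None
    tied: bool = False


def dominant_species(control_df: pd.DataFrame, site_id: str | None = None) -> DominanceRecord:
    """Most abundant species of a site's control plots at the endpoint.

    Dominance basis: summed control abundance divided by the number of
    control plots.  Ties are broken lexicographically by species id and
    logged.
    """
    ctl = control_df[control_df["is_control"]] if "is_control" in control_df.columns else control_df
    if ctl.empty or not (ctl["abundance"] > 0).any():
        raise ValueError("no control plots with positive abundance")
    n_plots = ctl.groupby(["block_id", "plot_id"]).ngroups
    means = (ctl.groupby("species_id")["abundance"].sum() / n_plots).sort_index()
    top = means.max()
    winners = means[means == top].index.tolist()
    tied = len(winners) > 1
    if tied:
        logger.warning("dominance tie among %s; taking %s", winners, winners[0])
    return DominanceRecord(
        site_id=site_id if site_id is not None else str(ctl.iloc[0].get("experiment_id", "")),
        dominant_species=winners[0],
        basis=float(top),
        tied=tied,
    )


@dataclass
class MixedLogisticFit:
    coefficients: dict
    random_sd: float
    log_likelihood: float
    chisq: float = np.nan
    p_value: float = np.nan
    converged: bool = False
    separation_flag: bool = False
    n_obs: int = 0


def _mixed_logit_ll(params, y, X, group_idx, n_groups, nodes, weights, penalty=1e-4):
    """Marginal log-likelihood of a random-intercept logistic model.

    The study-level intercept is integrated out with Gauss-Hermite
    quadrature; a tiny L2 penalty on the slopes keeps separated data sets
    finite without materially shifting regular estimates.
    """
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta = X @ beta  # (n,)
    # (n, q): linear predictor at each quadrature node
    u = np.sqrt(2.0) * sigma * nodes
    eta_q = eta[:, None] + u[None, :]
    logp = -np.logaddexp(0.0, -eta_q)
    log1mp = -np.logaddexp(0.0, eta_q)
    contrib = np.where(y[:, None] > 0, logp, log1mp)
    group_log = np.zeros((n_groups, len(nodes)))
    np.add.at(group_log, group_idx, contrib)
    # log sum_k w_k/sqrt(pi) * exp(group_log[, k])
    lw = np.log(weights / np.sqrt(np.pi))
    ll = np.sum(
        np.logaddexp.reduce(group_log + lw[None, :], axis=1)
    )
    return ll - penalty * float(beta @ beta)


def _fit_mixed_logit(y, X, group_idx, n_groups, n_quad=31):
    nodes, weights = roots_hermite(n_quad)
    x0 = np.zeros(X.shape[1] + 1)
    x0[-1] = np.log(0.5)

    def nll(p):
        return -_mixed_logit_ll(p, y, X, group_idx, n_groups, nodes, weights)

    opt = minimize(nll, x0, method="BFGS", options={"maxiter": 1000, "gtol": 1e-7})
    if not opt.success:
        opt = minimize(nll, opt.x, method="Nelder-Mead",
                       options={"maxiter": 5000, "fatol": 1e-10})
    return opt.x, -float(opt.fun), bool(opt.success)


def fit_lifehistory_model(
    meta: pd.DataFrame, climate: str = "PET", standardize: bool = True
) -> MixedLogisticFit:
    """Mixed-effects logistic regression of monocarpy on climate.

    Response: dominant species monocarpic (1) vs polycarpic (0), one row
    per experiment; fixed effect: the climate covariate (2-SD standardised
    by default); random intercept: study, integrated by Gauss-Hermite
    quadrature.  The reported chi-square is the likelihood-ratio statistic
    of the climate term against the intercept-only model (1 df).
    """
    df = meta.dropna(subset=[climate, "dominant_life_history"]).copy()
    df = df[df["dominant_life_history"].isin(["monocarpic", "polycarpic"])]
    y = (df["dominant_life_history"] == "monocarpic").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both life-history classes must be present")
    x = df[climate].to_numpy(dtype=float)
    if standardize:
        x = (x - x.mean()) / (2.0 * x.std(ddof=1))
    X = np.column_stack([np.ones_like(x), x])
    groups, group_idx = np.unique(df["study_id"].to_numpy(), return_inverse=True)

    params, llf, ok = _fit_mixed_logit(y, X, group_idx, len(groups))
    params0, llf0, ok0 = _fit_mixed_logit(y, X[:, :1], group_idx, len(groups))
    chisq = max(2.0 * (llf - llf0), 0.0)
    fit = MixedLogisticFit(
        coefficients={"Intercept": float(params[0]), climate: float(params[1])},
        random_sd=float(np.exp(params[-1])),
        log_likelihood=llf,
        chisq=float(chisq),
        p_value=float(stats.chi2.sf(chisq, df=1)),
        converged=ok and ok0,
        separation_flag=bool(abs(params[1]) > 15),
        n_obs=len(y),
    )
    if fit.separation_flag:
        logger.warning("possible separation: climate slope %.1f", params[1])
    return fit


def lifehistory_group_test(
    effects: pd.DataFrame,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    metrics_scales: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Monocarpic vs polycarpic difference in each effect size.

    Per metric x scale: mixed model lrr ~ life_history with a study random
    intercept; the group difference (monocarpic minus polycarpic) gets a
    parametric-bootstrap 95% CI, significant when the CI excludes zero.
    """
    rng = np.random.default_rng() if rng is None else rng
    if metrics_scales is None:
        metrics_scales = (
            effects[["metric", "scale"]].drop_duplicates().itertuples(index=False)
        )
        metrics_scales = [(m, s) for m, s in metrics_scales]
    out = []
    for metric, scale in metrics_scales:
        df = effects[
            (effects["metric"] == metric)
            & (effects["scale"] == scale)
            & effects["dominant_life_history"].isin(["monocarpic", "polycarpic"])
        ].copy()
        if df.empty or df["dominant_life_history"].nunique() < 2:
            raise ValueError(f"both life-history groups required for {metric}/{scale}")
        df["mono"] = (df["dominant_life_history"] == "monocarpic").astype(float)
        est, lo, hi = _group_diff_boot(df, n_boot, rng)
        out.append(
            {
                "metric": metric,
                "scale": scale,
                "difference": est,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
                "n_obs": len(df),
            }
        )
    return pd.DataFrame(out)


def _fit_group_model(df: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM.from_formula(
            "lrr ~ mono", data=df, groups=df["study_id"], re_formula="1"
        )
        try:
            res = model.fit(reml=True, method="lbfgs")
        except (np.linalg.LinAlgError, ValueError):
            res = model.fit(reml=True, method="powell")
    return res


def _group_diff_boot(df: pd.DataFrame, n_boot: int, rng: np.random.Generator):
    res = _fit_group_model(df)
    est = float(res.fe_params["mono"])
    X = res.model.exog
    beta = np.asarray(res.fe_params)
    sd_study = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
    sd_resid = float(np.sqrt(res.scale))
    studies, inv = np.unique(df["study_id"].to_numpy(), return_inverse=True)
    draws = np.full(n_boot, np.nan)
    work = df.copy()
    for b in range(n_boot):
        y = X @ beta + rng.normal(0, sd_study, len(studies))[inv] + rng.normal(
            0, sd_resid, len(df)
        )
        work["lrr"] = y
        try:
            bres = _fit_group_model(work)
            draws[b] = float(bres.fe_params["mono"])
        except (np.linalg.LinAlgError, ValueError):
            continue
    lo, hi = np.nanpercentile(draws, [2.5, 97.5])
    return est, float(lo), float(hi)


@dataclass
class CodependenceReport:
    study_summary: pd.DataFrame = None
    effect_design_correlations: pd.DataFrame = None
    moderator_design_correlations: pd.DataFrame = None
    influential_studies: dict = field(default_factory=dict)
    flagged_correlations: list = field(default_factory=list)


def spake_codependence(
    effects: pd.DataFrame,
    meta: pd.DataFrame,
    r_threshold: float = 0.5,
    leave_one_out: bool = True,
) -> CodependenceReport:
    """Study-level scale-dependence screen.

    Summarises each study (mean and variance of every effect size, sample
    size, plot size), correlates those with the design variables and with
    the moderators, flags |r| >= threshold, and — via leave-one-out refits
    of the lrr ~ delta_P model — flags studies whose removal flips a
    fitted slope's sign.
    """
    if effects["study_id"].nunique() < 3:
        raise ValueError("codependence screen needs at least 3 studies")
    summ = (
        effects.groupby(["study_id", "metric", "scale"])
        .agg(mean_lrr=("lrr", "mean"), var_lrr=("lrr", "var"), n=("lrr", "size"))
        .reset_index()
    )
    design = (
        effects.groupby("study_id")
        .agg(sample_size=("lrr", "size"), plot_size=("plot_size", "mean"))
        .reset_index()
    )
    summ = summ.merge(design, on="study_id")

    def _corr(sub: pd.DataFrame, a: str, b: str) -> float:
        if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
            return np.nan
        return float(sub[a].corr(sub[b]))

    rows = []
    for (metric, scale), grp in summ.groupby(["metric", "scale"]):
        for stat in ("mean_lrr", "var_lrr"):
            for dv in ("sample_size", "plot_size"):
                sub = grp[[stat, dv]].dropna()
                r = _corr(sub, stat, dv)
                rows.append(
                    {"metric": metric, "scale": scale, "statistic": stat,
                     "design_var": dv, "r": r}
                )
    eff_corr = pd.DataFrame(rows)

    mod_cols = [c for c in ("delta_P", "MAP", "PET", "duration") if c in meta.columns]
    study_mod = meta.groupby("study_id")[mod_cols].mean().reset_index()
    var_overall = (
        effects.groupby("study_id")["lrr"].var().rename("var_lrr").reset_index()
    )
    mod_df = study_mod.merge(design, on="study_id").merge(var_overall, on="study_id")
    rows = []
    for mod in mod_cols:
        for dv in ("var_lrr", "sample_size", "plot_size"):
            sub = mod_df[[mod, dv]].dropna()
            rows.append({"moderator": mod, "design_var": dv, "r": _corr(sub, mod, dv)})
    mod_corr = pd.DataFrame(rows)

    flagged = []
    for _, row in eff_corr.dropna(subset=["r"]).iterrows():
        if abs(row["r"]) >= r_threshold:
            flagged.append(
                (row["metric"], row["scale"], row["statistic"], row["design_var"], row["r"])
            )
    for _, row in mod_corr.dropna(subset=["r"]).iterrows():
        if abs(row["r"]) >= r_threshold:
            flagged.append(("moderator", row["moderator"], row["design_var"], row["r"]))

    influential: dict = {}
    if leave_one_out:
        from .inference import prepare_effects

        for (metric, scale) in effects[["metric", "scale"]].drop_duplicates().itertuples(
            index=False
        ):
            try:
                df, _ = prepare_effects(effects, metric, scale)
            except ValueError:
                continue
            if df.empty or df["study_id"].nunique() < 3:
                continue
            spec = ModelSpec(fixed_terms=("delta_P_s",), scale=scale)
            full = fit_lmm(df, spec, reml=True)
            base_sign = np.sign(full.coefficients.get("delta_P_s", np.nan))
            flips = []
            for study in sorted(df["study_id"].unique()):
                sub = df[df["study_id"] != study]
                if sub["study_id"].nunique() < 2:
                    continue
                loo = fit_lmm(sub, spec, reml=True)
                s = np.sign(loo.coefficients.get("delta_P_s", np.nan))
                if np.isfinite(s) and s != base_sign:
                    flips.append(study)
            if flips:
                influential[(metric, scale)] = flips
    return CodependenceReport(
        study_summary=summ,
        effect_design_correlations=eff_corr,
        moderator_design_correlations=mod_corr,
        influential_studies=influential,
        flagged_correlations=flagged,
    )


def weighted_refit(
    df: pd.DataFrame,
    spec: ModelSpec,
    n_column: str = "n_plots_treatment",
):
    """Sensitivity refit with per-row weights sqrt(sample size).

    Each row's residual precision is scaled by sqrt(n); the fit uses the
    direct marginal-likelihood solver (statsmodels' mixed models carry no
    per-row residual weights).  Returns (weighted result dict, comparison
    with the unweighted fit: per-coefficient sign agreement).
    """
    n = pd.to_numeric(df[n_column])
    if (n <= 0).any():
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(n.to_numpy(dtype=float))

    from patsy import dmatrices

    ymat, X = dmatrices(spec.formula, df, return_type="dataframe")
    groups = [df["study_id"].to_numpy()]
    if "site_uid" in df.columns:
        groups.append(df["site_uid"].to_numpy())
    if spec.scale in ("local", "turnover") and "block_uid" in df.columns:
        groups.append(df["block_uid"].to_numpy())
    beta, variances, llf, ok = fit_marginal_lmm(
        ymat.to_numpy().ravel(), X.to_numpy(), groups, weights=w, reml=True
    )
    names = list(X.columns)
    weighted = {
        "coefficients": dict(zip(names, map(float, beta))),
        "variances": variances,
        "log_likelihood": llf,
        "converged": ok,
        "weights_column": n_column,
    }
    unweighted = fit_lmm(df, spec, reml=True)
    agree = {
        k: bool(np.sign(weighted["coefficients"][k]) == np.sign(v))
        for k, v in unweighted.coefficients.items()
        if k in weighted["coefficients"] and v != 0
    }
    return weighted, {"unweighted": unweighted, "sign_agreement": agree}
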