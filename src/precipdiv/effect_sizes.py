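"""Log response ratios of diversity metrics at local, site and turnover scales.

The effect-size currency of the synthesis is the log response ratio,
LRR = ln(treatment) - ln(control): negative values mean the precipitation
treatment decreased the response.  Because the ratio is taken within an
experiment, the abundance unit (cover, biomass or point-intercept hits)
cancels.

Granularity follows the blocked experimental designs: local-scale and
turnover-scale LRRs are computed per block (within-block means of plot
metrics; unblocked designs are a single block), while site-scale LRRs are
one per experiment, built from treatment-level pooled/rarefied metrics.
The turnover LRR per block contrasts each arm's beta ratio, i.e. the arm's
site-scale metric divided by the block's local mean.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .diversity_metrics import (
    DiversityProfile,
    plot_richness,
    plot_total_abundance,
    s_pie,
    treatment_summary,
)

__all__ = [
    "lrr",
    "treatment_plots",
    "compute_treatment_profiles",
    "block_effect_sizes",
    "site_effect_sizes",
    "assemble_effect_table",
]

logger = logging.getLogger(__name__)

_METRICS_LOCAL = ("S", "S_PIE", "total_cover")
_METRICS_SITE = ("S", "S_PIE")


def lrr(treatment_value: float, control_value: float) -> float:
    """ln(treatment) - ln(control); both inputs must be positive."""
    if not (treatment_value > 0 and control_value > 0):
        raise ValueError(
            f"LRR undefined for nonpositive values ({treatment_value}, {control_value})"
        )
    return math.log(treatment_value) - math.log(control_value)


def _safe_lrr(t, c, context: str):
    """LRR or None; zero/missing metrics drop the row with a logged warning."""
    if t is None or c is None or not np.isfinite(t) or not np.isfinite(c) or t <= 0 or c <= 0:
        logger.warning("dropping undefined LRR (%s): treatment=%s control=%s", context, t, c)
        return None
    return lrr(t, c)


def treatment_plots(exp_df: pd.DataFrame) -> dict:
    """Nest one experiment's rows as {treatment: {block: {plot: Series}}}."""
    out: dict = {}
    for (trt, block, plot), grp in exp_df.groupby(
        ["treatment_id", "block_id", "plot_id"], sort=True
    ):
        vec = grp.groupby("species_id")["abundance"].sum()
        out.setdefault(trt, {}).setdefault(block, {})[plot] = vec
    return out


def compute_treatment_profiles(
    community: pd.DataFrame, n_ref: int = 3, n_boot: int = 1000, seed: int | None = 0
) -> dict:
    """DiversityProfile per (experiment_id, treatment_id), deterministic in seed."""
    rng = np.random.default_rng(seed)
    profiles: dict[tuple, DiversityProfile] = {}
    for (exp_id, trt_id), grp in community.groupby(
        ["experiment_id", "treatment_id"], sort=True
    ):
        plots = [
            g.groupby("species_id")["abundance"].sum()
            for _, g in grp.groupby(["block_id", "plot_id"], sort=True)
        ]
        with np.errstate(all="ignore"):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                profiles[(exp_id, trt_id)] = treatment_summary(
                    plots, n_ref=n_ref, n_boot=n_boot, rng=rng, treatment_key=(exp_id, trt_id)
                )
    return profiles


def _block_local_means(block_plots: dict) -> dict:
    """Within-block means of the per-plot metrics."""
    vals = {m: [] for m in _METRICS_LOCAL}
    for vec in block_plots.values():
        vals["S"].append(plot_richness(vec))
        vals["S_PIE"].append(s_pie(vec))
        vals["total_cover"].append(plot_total_abundance(vec))
    return {m: float(np.nanmean(v)) if len(v) else np.nan for m, v in vals.items()}


def block_effect_sizes(
    exp_df: pd.DataFrame, profiles: dict, exp_id: str
) -> list[dict]:
    """Local- and turnover-scale LRR rows for one experiment, per block x treatment."""
    nested = treatment_plots(exp_df)
    ctl_ids = exp_df.loc[exp_df["is_control"], "treatment_id"].unique()
    if len(ctl_ids) != 1:
        raise ValueError(f"experiment {exp_id} must have exactly one control treatment")
    ctl = ctl_ids[0]
    rows: list[dict] = []
    for trt in sorted(nested):
        if trt == ctl:
            continue
        prof_t = profiles.get((exp_id, trt))
        prof_c = profiles.get((exp_id, ctl))
        gamma = {
            "S": (prof_t.gamma_S_boot_mean, prof_c.gamma_S_boot_mean),
            "S_PIE": (prof_t.gamma_SPIE, prof_c.gamma_SPIE),
        }
        blocks = sorted(set(nested[trt]) & set(nested.get(ctl, {})))
        skipped = set(nested[trt]) ^ set(nested.get(ctl, {}))
        for b in skipped:
            logger.warning(
                "experiment %s block %s lacks one arm; block skipped", exp_id, b
            )
        for b in blocks:
            loc_t = _block_local_means(nested[trt][b])
            loc_c = _block_local_means(nested[ctl][b])
            n_t, n_c = len(nested[trt][b]), len(nested[ctl][b])
            for metric in _METRICS_LOCAL:
                val = _safe_lrr(
                    loc_t[metric], loc_c[metric], f"{exp_id}/{b}/{metric}/local"
                )
                if val is not None:
                    rows.append(
                        {
                            "experiment_id": exp_id,
                            "treatment_id": trt,
                            "block_id": b,
                            "metric": metric,
                            "scale": "local",
                            "lrr": val,
                            "n_plots_treatment": n_t,
                            "n_plots_control": n_c,
                        }
                    )
            for metric in _METRICS_SITE:
                g_t, g_c = gamma[metric]
                if not (np.isfinite(g_t) and np.isfinite(g_c)):
                    continue  # site-scale metric unavailable (too few plots)
                a_t, a_c = loc_t[metric], loc_c[metric]
                if not (a_t and a_c and np.isfinite(a_t) and np.isfinite(a_c)):
                    continue
                val = _safe_lrr(
                    g_t / a_t, g_c / a_c, f"{exp_id}/{b}/{metric}/turnover"
                )
                if val is not None:
                    rows.append(
                        {
                            "experiment_id": exp_id,
                            "treatment_id": trt,
                            "block_id": b,
                            "metric": metric,
                            "scale": "turnover",
                            "lrr": val,
                            "n_plots_treatment": n_t,
                            "n_plots_control": n_c,
                        }
                    )
    return rows


def site_effect_sizes(exp_df: pd.DataFrame, profiles: dict, exp_id: str) -> list[dict]:
    """Site-scale LRR rows: one per (non-control treatment, metric)."""
    ctl_ids = exp_df.loc[exp_df["is_control"], "treatment_id"].unique()
    if len(ctl_ids) != 1:
        raise ValueError(f"experiment {exp_id} must have exactly one control treatment")
    ctl = ctl_ids[0]
    trts = sorted(set(exp_df["treatment_id"]) - {ctl})
    rows = []
    prof_c = profiles.get((exp_id, ctl))
    for trt in trts:
        prof_t = profiles.get((exp_id, trt))
        for metric, (g_t, g_c) in {
            "S": (prof_t.gamma_S_boot_mean, prof_c.gamma_S_boot_mean),
            "S_PIE": (prof_t.gamma_SPIE, prof_c.gamma_SPIE),
        }.items():
            if not (np.isfinite(g_t) and np.isfinite(g_c)):
                logger.warning(
                    "experiment %s metric %s: site-scale metric missing, row omitted",
                    exp_id,
                    metric,
                )
                continue
            val = _safe_lrr(g_t, g_c, f"{exp_id}/{metric}/site")
            if val is not None:
                rows.append(
                    {
                        "experiment_id": exp_id,
                        "treatment_id": trt,
                        "block_id": None,
                        "metric": metric,
                        "scale": "site",
                        "lrr": val,
                        "n_plots_treatment": prof_t.n_plots,
                        "n_plots_control": prof_c.n_plots,
                    }
                )
    return rows


def assemble_effect_table(
    community: pd.DataFrame,
    meta: pd.DataFrame,
    n_ref: int = 3,
    n_boot: int = 1000,
    seed: int | None = 0,
    profiles: dict | None = None,
) -> pd.DataFrame:
    """Full effect-size table for a dataset, joined to experiment covariates.

    Experiments missing a metadata row keep their effect-size rows with
    missing covariates and ``meta_missing = True``.
    """
    if profiles is None:
        profiles = compute_treatment_profiles(community, n_ref=n_ref, n_boot=n_boot, seed=seed)
    rows: list[dict] = []
    for exp_id, grp in community.groupby("experiment_id", sort=True):
        rows.extend(block_effect_sizes(grp, profiles, exp_id))
        rows.extend(site_effect_sizes(grp, profiles, exp_id))
    effects = pd.DataFrame(rows)
    if effects.empty:
        return effects

    cov_cols = [
        c
        for c in (
            "study_id",
            "site_id",
            "delta_P",
            "direction",
            "duration",
            "MAP",
            "PET",
            "plot_size",
            "dominant_life_history",
        )
        if c in meta.columns
    ]
    merged = effects.merge(
        meta[["experiment_id"] + cov_cols], on="experiment_id", how="left"
    )
    merged["meta_missing"] = ~merged["experiment_id"].isin(meta["experiment_id"])
    if merged["meta_missing"].any():
        logger.warning(
            "%d effect-size rows lack experiment metadata",
            int(merged["meta_missing"].sum()),
        )
    front = [
        "study_id",
        "site_id",
        "experiment_id",
        "treatment_id",
        "block_id",
        "metric",
        "scale",
        "lrr",
    ]
    ordered = [c for c in front if c in merged.columns] + [
        c for c in merged.columns if c not in front
    ]
    return merged[ordered]
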