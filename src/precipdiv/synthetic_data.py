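"""Synthetic community-experiment datasets with known ground truth.

Emulates the structure of a multi-study synthesis of precipitation
manipulation experiments: studies contain sites (one experiment per site),
experiments contain blocks pairing treatment and control plots, and plots
hold individual-based community samples drawn from a species abundance
distribution (SAD).

Treatment effects are injected on three axes:

* density — the expected number of individuals per treatment plot is the
  control density times ``exp(eta)``, where eta is a linear predictor in the
  scaled manipulation magnitude (delta_P), its interaction with scaled mean
  annual precipitation (MAP), and nested study/site/block random effects;
* evenness — the treatment arm samples from a SAD whose shape parameter is
  re-calibrated (by bisection) so that the expected S_PIE of the treatment
  community is exp(target) times that of the control community;
* turnover — an ``aggregation`` knob switches plot filling from multinomial
  (0) to Dirichlet-multinomial (clumped) sampling, raising plot-to-plot
  compositional heterogeneity.

Counts are generated internally and emitted as percent cover using a fixed
0.5% quantum per individual, mimicking cover data while keeping
individual-based sampling well defined.  A second generator draws log
response ratios directly from the hierarchical linear model used downstream,
for exact inference testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diversity_metrics import s_pie

__all__ = [
    "ScenarioConfig",
    "ExperimentContext",
    "sample_sad",
    "calibrate_sad_shape",
    "generate_community_experiment",
    "generate_synthesis_dataset",
    "generate_effectsize_table",
    "COVER_QUANTUM",
]

COVER_QUANTUM = 0.5  # percent cover per individual


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic synthesis dataset.

    Defaults mirror the shape of the compiled dataset the pipeline targets:
    23 studies contributing 72 experiments, blocked designs averaging ~6.5
    blocks per experiment (so roughly 460 block-level effect sizes), at
    least 3 replicate plots per treatment, background MAP spanning
    225-1574 mm per year and manipulations up to +/-80% of MAP.
    """

    n_studies: int = 23
    n_experiments_total: int | None = 72
    sites_per_study: tuple[int, int] = (1, 6)
    blocks_per_experiment: tuple[int, int] = (3, 10)
    plots_per_treatment_per_block: int = 1
    species_pool_size: int = 40
    sad_family: str = "lognormal"
    sad_shape: float = 1.0
    individuals_per_plot_control: int = 100
    delta_P_range: tuple[float, float] = (-80.0, 80.0)
    delta_P_min_abs: float = 5.0
    MAP_range: tuple[float, float] = (225.0, 1574.0)
    PET_range: tuple[float, float] = (400.0, 1800.0)
    duration_range: tuple[int, int] = (1, 15)
    plot_size_range: tuple[float, float] = (0.08, 2.5)
    beta_density: float = 0.3
    beta_evenness: float = 0.15
    beta_interaction: float = -0.2
    beta_lifehistory: float = 1.5
    sd_study: float = 0.1
    sd_site: float = 0.1
    sd_block: float = 0.1
    sd_resid: float = 0.2
    aggregation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1 or self.species_pool_size < 1:
            raise ValueError("counts must be >= 1")
        if self.plots_per_treatment_per_block < 1:
            raise ValueError("plots_per_treatment_per_block must be >= 1")
        for name in ("sd_study", "sd_site", "sd_block", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.aggregation < 0:
            raise ValueError("aggregation must be >= 0")

    # -- covariate scaling used when injecting effects ------------------
    def scale_delta_P(self, delta_P):
        """delta_P in percent of MAP -> one unit per 100% manipulation."""
        return np.asarray(delta_P, dtype=float) / 100.0

    def scale_MAP(self, MAP):
        """MAP -> 0 at the range midpoint, +/-1 at the range ends."""
        lo, hi = self.MAP_range
        return (np.asarray(MAP, dtype=float) - (lo + hi) / 2.0) / ((hi - lo) / 2.0)

    def scale_PET(self, PET):
        lo, hi = self.PET_range
        return (np.asarray(PET, dtype=float) - (lo + hi) / 2.0) / ((hi - lo) / 2.0)


def sample_sad(pool_size: int, family: str, shape: float, rng: np.random.Generator):
    """Relative-abundance vector of a species pool, sorted descending.

    ``lognormal``: abundances proportional to exp(shape * z) with z standard
    normal (shape = 0 gives a perfectly even pool).  ``geometric``:
    abundances proportional to shape**i, requiring 0 < shape < 1.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if family == "lognormal":
        if shape < 0:
            raise ValueError("lognormal shape (sigma) must be >= 0")
        z = rng.standard_normal(pool_size)
        p = np.exp(shape * np.sort(z)[::-1])
    elif family == "geometric":
        if not (0 < shape < 1):
            raise ValueError("geometric ratio must lie in (0, 1)")
        p = shape ** np.arange(pool_size, dtype=float)
    else:
        raise ValueError(f"unknown SAD family {family!r}")
    return p / p.sum()


def _sad_at_shape(family: str, shape: float, z: np.ndarray | None, pool_size: int):
    if family == "lognormal":
        p = np.exp(shape * z)
    else:
        shape = min(max(shape, 1e-9), 1 - 1e-9)
        p = shape ** np.arange(pool_size, dtype=float)
    return p / p.sum()


def calibrate_sad_shape(
    family: str,
    base_shape: float,
    target_lrr_spie: float,
    z: np.ndarray | None = None,
    pool_size: int | None = None,
    rel_tol: float = 1e-3,
):
    """Shape parameter whose SAD has S_PIE = exp(target) x base S_PIE.

    For the lognormal family the realised z-scores are held fixed and only
    sigma is adjusted, so the calibration is deterministic given the draw.
    S_PIE is monotone decreasing in lognormal sigma and increasing in the
    geometric ratio; bisection converges to the stated relative tolerance.
    Targets outside the attainable range [1, pool size] are clamped.
    """
    if pool_size is None:
        pool_size = len(z)
    base = s_pie(_sad_at_shape(family, base_shape, z, pool_size))
    target = base * np.exp(target_lrr_spie)
    target = min(max(target, 1.0 + 1e-9), pool_size * (1 - 1e-12))
    if abs(target - base) / base <= rel_tol:
        return base_shape

    def val(shape):
        return s_pie(_sad_at_shape(family, shape, z, pool_size))

    if family == "lognormal":
        lo, hi = 0.0, max(base_shape, 0.5)
        while val(hi) > target and hi < 64:
            hi *= 2.0
        # val is decreasing: val(lo)=pool >= target >= val(hi)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if val(mid) > target:
                lo = mid
            else:
                hi = mid
            if abs(val(mid) - target) / target <= rel_tol * 0.1:
                break
        return 0.5 * (lo + hi)
    else:
        lo, hi = 1e-9, 1 - 1e-9
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if val(mid) < target:
                lo = mid
            else:
                hi = mid
            if abs(val(mid) - target) / target <= rel_tol * 0.1:
                break
        return 0.5 * (lo + hi)


def _fill_plot(n_ind: int, p: np.ndarray, aggregation: float, rng: np.random.Generator):
    """Species counts for one plot: multinomial or Dirichlet-multinomial."""
    if n_ind <= 0:
        return np.zeros_like(p, dtype=np.int64)
    if aggregation > 0:
        q = rng.dirichlet(p / aggregation)
        return rng.multinomial(n_ind, q)
    return rng.multinomial(n_ind, p)


def _expected_richness(lam: float, p: np.ndarray, aggregation: float) -> float:
    """Expected plot richness under the generating scheme.

    Multinomial filling with Poisson plot totals thins each species to an
    independent Poisson(lam * p_i), so E[S] = sum(1 - exp(-lam p_i)).  For
    Dirichlet-multinomial filling the absence probability has the closed
    beta-binomial form, evaluated at N = round(lam).
    """
    from scipy.special import gammaln

    if aggregation <= 0:
        return float(np.sum(1.0 - np.exp(-lam * p)))
    alpha = p / aggregation
    A = alpha.sum()
    N = max(int(round(lam)), 1)
    log_p0 = (
        gammaln(A) + gammaln(A - alpha + N) - gammaln(A + N) - gammaln(A - alpha)
    )
    return float(np.sum(1.0 - np.exp(log_p0)))


@dataclass
class ExperimentContext:
    """Covariates and realised random effects for one experiment."""

    study_id: str
    site_id: str
    experiment_id: str
    delta_P: float
    MAP: float
    PET: float
    duration: int
    plot_size: float
    dominant_life_history: str
    u_study: float = 0.0
    u_site: float = 0.0


def generate_community_experiment(
    config: ScenarioConfig, ctx: ExperimentContext, rng: np.random.Generator
):
    """One experiment's plot-level community rows, metadata row and truth record.

    The treatment arm's expected plot density is the control density times
    exp(eta), eta = beta_density * dP_s + beta_interaction * dP_s * MAP_s +
    u_study + u_site (+ block effect); its SAD is calibrated so the expected
    S_PIE log-ratio equals beta_evenness * dP_s.
    """
    dP_s = float(config.scale_delta_P(ctx.delta_P))
    MAP_s = float(config.scale_MAP(ctx.MAP))
    eta_dens = (
        config.beta_density * dP_s
        + config.beta_interaction * dP_s * MAP_s
        + ctx.u_study
        + ctx.u_site
    )
    eta_even = config.beta_evenness * dP_s

    z = None
    if config.sad_family == "lognormal":
        z = np.sort(rng.standard_normal(config.species_pool_size))[::-1]
    p_control = _sad_at_shape(
        config.sad_family, config.sad_shape, z, config.species_pool_size
    )
    trt_shape = calibrate_sad_shape(
        config.sad_family, config.sad_shape, eta_even, z, config.species_pool_size
    )
    p_treatment = _sad_at_shape(
        config.sad_family, trt_shape, z, config.species_pool_size
    )

    n_blocks = int(rng.integers(config.blocks_per_experiment[0], config.blocks_per_experiment[1] + 1))
    lam0 = float(config.individuals_per_plot_control)
    species = np.array([f"sp{i:03d}" for i in range(config.species_pool_size)])

    rows = []
    block_effects = rng.normal(0.0, config.sd_block, size=n_blocks) if config.sd_block > 0 else np.zeros(n_blocks)
    for b in range(n_blocks):
        block_id = f"{ctx.experiment_id}-b{b + 1}"
        for arm, trt_id, is_ctl, p_vec in (
            ("c", "control", True, p_control),
            ("t", "trt", False, p_treatment),
        ):
            for r in range(config.plots_per_treatment_per_block):
                eps = rng.normal(0.0, config.sd_resid) if config.sd_resid > 0 else 0.0
                lam = lam0 if is_ctl else lam0 * np.exp(eta_dens + block_effects[b] + eps)
                n_ind = int(rng.poisson(lam))
                counts = _fill_plot(n_ind, p_vec, config.aggregation, rng)
                present = counts > 0
                for sp, cnt in zip(species[present], counts[present]):
                    rows.append(
                        {
                            "study_id": ctx.study_id,
                            "experiment_id": ctx.experiment_id,
                            "treatment_id": trt_id,
                            "is_control": is_ctl,
                            "block_id": block_id,
                            "plot_id": f"{block_id}-{arm}{r + 1}",
                            "species_id": sp,
                            "abundance": float(cnt) * COVER_QUANTUM,
                            "abundance_unit": "cover",
                        }
                    )

    meta_row = {
        "study_id": ctx.study_id,
        "experiment_id": ctx.experiment_id,
        "site_id": ctx.site_id,
        "delta_P": ctx.delta_P,
        "duration": ctx.duration,
        "MAP": ctx.MAP,
        "PET": ctx.PET,
        "plot_size": ctx.plot_size,
        "dominant_life_history": ctx.dominant_life_history,
    }

    lam_trt = lam0 * np.exp(eta_dens)
    e_s_ctl = _expected_richness(lam0, p_control, config.aggregation)
    e_s_trt = _expected_richness(lam_trt, p_treatment, config.aggregation)
    truth = {
        "experiment_id": ctx.experiment_id,
        "lrr_total_abundance": eta_dens,
        "lrr_local_SPIE": eta_even,
        "lrr_local_S": float(np.log(e_s_trt) - np.log(e_s_ctl)),
        "u_study": ctx.u_study,
        "u_site": ctx.u_site,
        "n_blocks": n_blocks,
        "dominant_species": "sp000",
        "treatment_sad_shape": float(trt_shape),
        "delta_P_scaled": dP_s,
        "MAP_scaled": MAP_s,
    }
    return rows, meta_row, truth


def _allocate_experiments(config: ScenarioConfig, rng: np.random.Generator) -> list[int]:
    if config.n_experiments_total is not None:
        total = config.n_experiments_total
        if total < config.n_studies:
            raise ValueError("n_experiments_total must be >= n_studies")
        base = total // config.n_studies
        extra = total - base * config.n_studies
        alloc = [base + (1 if i < extra else 0) for i in range(config.n_studies)]
        return alloc
    lo, hi = config.sites_per_study
    return [int(rng.integers(lo, hi + 1)) for _ in range(config.n_studies)]


def generate_synthesis_dataset(config: ScenarioConfig):
    """Full multi-study dataset: (community table, metadata table, truth records).

    Reproducible bit-exactly from (config, config.seed): a single seeded
    stream drives every draw in a fixed iteration order.
    """
    rng = np.random.default_rng(config.seed)
    alloc = _allocate_experiments(config, rng)

    all_rows: list[dict] = []
    meta_rows: list[dict] = []
    truths: dict[str, dict] = {}
    for s_idx, n_sites in enumerate(alloc):
        study_id = f"study{s_idx + 1:02d}"
        u_study = rng.normal(0.0, config.sd_study) if config.sd_study > 0 else 0.0
        for k in range(n_sites):
            site_id = f"{study_id}-site{k + 1}"
            exp_id = f"{site_id}-exp"
            u_site = rng.normal(0.0, config.sd_site) if config.sd_site > 0 else 0.0
            lo, hi = config.delta_P_range
            delta_P = 0.0
            while abs(delta_P) < config.delta_P_min_abs:
                delta_P = float(rng.uniform(lo, hi))
            MAP = float(rng.uniform(*config.MAP_range))
            # PET loosely anti-correlated with MAP: dry sites have high
            # evaporative demand
            pet_lo, pet_hi = config.PET_range
            pet_mid = (pet_lo + pet_hi) / 2.0
            pet_half = (pet_hi - pet_lo) / 2.0
            PET = float(
                np.clip(
                    pet_mid
                    - 0.6 * pet_half * config.scale_MAP(MAP)
                    + rng.normal(0.0, 0.3 * pet_half),
                    pet_lo,
                    pet_hi,
                )
            )
            duration = int(rng.integers(config.duration_range[0], config.duration_range[1] + 1))
            plot_size = float(np.exp(rng.uniform(*np.log(config.plot_size_range))))
            p_mono = 1.0 / (1.0 + np.exp(-(config.beta_lifehistory * config.scale_PET(PET))))
            life = "monocarpic" if rng.uniform() < p_mono else "polycarpic"
            ctx = ExperimentContext(
                study_id=study_id,
                site_id=site_id,
                experiment_id=exp_id,
                delta_P=delta_P,
                MAP=MAP,
                PET=PET,
                duration=duration,
                plot_size=plot_size,
                dominant_life_history=life,
                u_study=u_study,
                u_site=u_site,
            )
            rows, meta_row, truth = generate_community_experiment(config, ctx, rng)
            all_rows.extend(rows)
            meta_rows.append(meta_row)
            truths[exp_id] = truth

    community = pd.DataFrame(all_rows)
    meta = pd.DataFrame(meta_rows)
    meta["direction"] = np.where(meta["delta_P"] > 0, "increase", "decrease")
    truths["_config"] = asdict(config)
    return community, meta, truths


def generate_effectsize_table(
    fixed_coefs,
    random_sds,
    n_studies: int,
    experiments_per_study: int,
    blocks_per_experiment: int,
    rng: np.random.Generator,
):
    """Draw block-level log response ratios directly from the hierarchical model.

    lrr = X beta + u_study + u_site + u_block + eps with covariates already
    on the analysis scale (so fitted coefficients are directly comparable to
    ``fixed_coefs``).  Coefficient order: intercept, delta_P_s, MAP_s,
    delta_P_s:MAP_s, duration_s — supply a prefix of any length.
    ``random_sds`` is (sd_study, sd_site, sd_block, sd_resid).
    """
    names = ["Intercept", "delta_P_s", "MAP_s", "delta_P_s:MAP_s", "duration_s"]
    coefs = np.asarray(fixed_coefs, dtype=float)
    if len(coefs) > len(names):
        raise ValueError(f"at most {len(names)} fixed coefficients supported")
    sd_study, sd_site, sd_block, sd_resid = [float(s) for s in random_sds]

    rows = []
    for s in range(n_studies):
        study_id = f"study{s + 1:02d}"
        u_study = rng.normal(0.0, sd_study) if sd_study > 0 else 0.0
        for e in range(experiments_per_study):
            site_id = f"{study_id}-site{e + 1}"
            exp_id = f"{site_id}-exp"
            u_site = rng.normal(0.0, sd_site) if sd_site > 0 else 0.0
            dp = rng.uniform(-1.0, 1.0)
            mp = rng.uniform(-1.0, 1.0)
            du = rng.uniform(-1.0, 1.0)
            x = np.array([1.0, dp, mp, dp * mp, du])[: len(coefs)]
            mu = float(x @ coefs)
            for b in range(blocks_per_experiment):
                u_block = rng.normal(0.0, sd_block) if sd_block > 0 else 0.0
                eps = rng.normal(0.0, sd_resid) if sd_resid > 0 else 0.0
                rows.append(
                    {
                        "study_id": study_id,
                        "site_id": site_id,
                        "experiment_id": exp_id,
                        "block_id": f"{exp_id}-b{b + 1}",
                        "lrr": mu + u_study + u_site + u_block + eps,
                        "delta_P_s": dp,
                        "MAP_s": mp,
                        "duration_s": du,
                        "direction": "increase" if dp > 0 else "decrease",
                        "metric": "S",
                        "scale": "local",
                        "n_plots_treatment": 1,
                        "n_plots_control": 1,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "coefficients": dict(zip(names[: len(coefs)], coefs.tolist())),
        "random_sds": {
            "study": sd_study,
            "site": sd_site,
            "block": sd_block,
            "residual": sd_resid,
        },
    }
    return table, truth
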