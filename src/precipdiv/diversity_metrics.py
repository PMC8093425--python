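"""Multi-scale diversity metrics for replicated community samples.

Each treatment in a precipitation-manipulation experiment is summarised at
three spatial scales:

* local (alpha): per-plot metrics averaged over the replicate plots;
* site (gamma): metrics of the pooled replicate set, with species richness
  rarefied down to a common number of plots so that treatments with unequal
  replication are comparable;
* turnover (beta): the site/local ratio, which for richness is Whittaker's
  beta diversity and captures plot-to-plot compositional heterogeneity.

Richness (S, Hill number q=0) weights rare and common species equally;
the effective number of species S_PIE = 1 / sum(p_i^2) (the inverse Simpson
concentration, Hill q=2) is dominated by the common species.  Sample-based
rarefaction uses the analytic hypergeometric form; the site-scale richness
entering turnover ratios is, in addition, the mean of rarefied richness over
bootstrap resamples of the plot list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "DiversityProfile",
    "plot_total_abundance",
    "plot_richness",
    "s_pie",
    "rarefied_richness",
    "bootstrap_rarefied_richness",
    "pooled_composition",
    "treatment_summary",
]


def _as_abundance_array(v) -> np.ndarray:
    """Coerce an abundance vector (Series, mapping or sequence) to an array."""
    if isinstance(v, Mapping):
        arr = np.asarray(list(v.values()), dtype=float)
    elif isinstance(v, pd.Series):
        arr = v.to_numpy(dtype=float)
    else:
        arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if arr.size and (arr < 0).any():
        raise ValueError("abundances must be nonnegative")
    return arr


def plot_total_abundance(v) -> float:
    """Summed abundance of a plot (total cover / biomass / hits)."""
    arr = _as_abundance_array(v)
    return float(arr.sum()) if arr.size else 0.0


def plot_richness(v) -> int:
    """Number of species with positive abundance."""
    arr = _as_abundance_array(v)
    return int((arr > 0).sum())


def s_pie(v) -> float:
    """Effective number of species of the probability of interspecific encounter.

    S_PIE = 1 / sum_i p_i^2 with p_i the relative abundances.  Equals S for a
    perfectly even community and decreases towards 1 with increasing dominance.
    Returns NaN for an all-zero (empty) vector; callers propagate this as a
    missing value rather than an exception.
    """
    arr = _as_abundance_array(v)
    total = arr.sum()
    if total <= 0:
        return float("nan")
    p = arr / total
    return float(1.0 / np.sum(p * p))


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n, dtype=float) + 1) - gammaln(k + 1) - gammaln(
        np.asarray(n, dtype=float) - k + 1
    )


def rarefied_richness(incidence: Sequence[int], N: int, n: int) -> float:
    """Expected richness when n of N plots are drawn without replacement.

    Analytic sample-based rarefaction: sum_i [1 - C(N - m_i, n) / C(N, n)]
    where m_i is the number of plots occupied by species i.  Species absent
    from every plot (m_i = 0) contribute nothing and may be omitted.
    """
    if n < 1 or n > N:
        raise ValueError(f"subsample size n={n} must satisfy 1 <= n <= N={N}")
    m = np.asarray(incidence, dtype=float)
    m = m[m > 0]
    if (m > N).any():
        raise ValueError("incidence count exceeds number of plots")
    if m.size == 0:
        return 0.0
    out = np.ones_like(m)
    keep = N - m >= n  # species present in too many plots are always sampled
    if keep.any():
        log_ratio = _log_comb(N - m[keep], n) - _log_comb(N, n)
        out[keep] = 1.0 - np.exp(log_ratio)
    return float(out.sum())


def pooled_composition(plots: Iterable) -> pd.Series:
    """Per-species abundance summed across plots of a treatment."""
    series = []
    for p in plots:
        if isinstance(p, Mapping) and not isinstance(p, pd.Series):
            p = pd.Series(p, dtype=float)
        elif not isinstance(p, pd.Series):
            raise TypeError("pooled_composition needs species-labelled vectors")
        series.append(p.astype(float))
    if not series:
        raise ValueError("pooled_composition requires at least one plot")
    pooled = pd.concat(series, axis=1).fillna(0.0).sum(axis=1)
    return pooled


def _incidence_from_matrix(mat: np.ndarray) -> np.ndarray:
    return (mat > 0).sum(axis=0)


def bootstrap_rarefied_richness(
    plots: Sequence, n: int, iters: int = 1000, rng: np.random.Generator | None = None
) -> float:
    """Mean rarefied richness over with-replacement resamples of the plot list.

    Each bootstrap iteration resamples N plots with replacement, recomputes
    the species-by-plot incidence and evaluates the analytic rarefaction at
    depth ``n``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    mat, _ = _plots_to_matrix(plots)
    N = mat.shape[0]
    if N < n:
        raise ValueError(f"need at least n={n} plots, got {N}")
    rng = np.random.default_rng() if rng is None else rng
    occ = mat > 0
    vals = np.empty(iters)
    for b in range(iters):
        idx = rng.integers(0, N, size=N)
        inc = occ[idx].sum(axis=0)
        vals[b] = rarefied_richness(inc[inc > 0], N, n)
    return float(vals.mean())


def _plots_to_matrix(plots: Sequence) -> tuple[np.ndarray, list]:
    """Stack plot vectors into a plots x species abundance matrix."""
    series = []
    for p in plots:
        if isinstance(p, Mapping) and not isinstance(p, pd.Series):
            p = pd.Series(p, dtype=float)
        if isinstance(p, pd.Series):
            series.append(p.astype(float))
        else:
            series.append(pd.Series(np.asarray(p, dtype=float)))
    df = pd.concat(series, axis=1).fillna(0.0)
    return df.to_numpy().T, list(df.index)


@dataclass
class DiversityProfile:
    """Per-treatment diversity summary at local, site and turnover scales."""

    treatment_key: tuple | str | None = None
    alpha_S: float = np.nan
    alpha_SPIE: float = np.nan
    gamma_S_rarefied: float = np.nan
    gamma_S_boot_mean: float = np.nan
    gamma_SPIE: float = np.nan
    beta_S: float = np.nan
    beta_SPIE: float = np.nan
    total_cover_mean: float = np.nan
    n_plots: int = 0
    n_ref: int = 3
    n_boot: int = 1000
    seed: int | None = None
    warnings: list = field(default_factory=list)


def treatment_summary(
    plots: Sequence,
    n_ref: int = 3,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    treatment_key=None,
    seed: int | None = None,
) -> DiversityProfile:
    """Full multi-scale profile of one treatment's replicate plots.

    Site-scale fields (gamma and the derived beta ratios) are left missing
    when fewer than ``n_ref`` plots are available: richness is only rarefied
    downwards, never extrapolated.
    """
    plots = list(plots)
    if not plots:
        raise ValueError("treatment has no plots")
    if rng is None:
        rng = np.random.default_rng(seed)

    mat, _species = _plots_to_matrix(plots)
    N = mat.shape[0]
    totals = mat.sum(axis=1)
    rich = (mat > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = mat / totals[:, None]
        spie_plots = np.where(totals > 0, 1.0 / np.einsum("ij,ij->i", p, p), np.nan)

    prof = DiversityProfile(
        treatment_key=treatment_key,
        alpha_S=float(np.mean(rich)),
        alpha_SPIE=float(np.nanmean(spie_plots)) if np.isfinite(spie_plots).any() else np.nan,
        total_cover_mean=float(np.mean(totals)),
        n_plots=N,
        n_ref=n_ref,
        n_boot=n_boot,
        seed=seed,
    )

    if N < n_ref:
        msg = f"insufficient replicates (n_plots={N} < n_ref={n_ref}); site-scale metrics omitted"
        prof.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
        return prof

    inc = _incidence_from_matrix(mat)
    prof.gamma_S_rarefied = rarefied_richness(inc[inc > 0], N, n_ref)
    prof.gamma_S_boot_mean = bootstrap_rarefied_richness(plots, n_ref, n_boot, rng)
    pooled = mat.sum(axis=0)
    prof.gamma_SPIE = s_pie(pooled)
    if prof.alpha_S > 0:
        prof.beta_S = prof.gamma_S_boot_mean / prof.alpha_S
    if prof.alpha_SPIE > 0:
        prof.beta_SPIE = prof.gamma_SPIE / prof.alpha_SPIE
    return prof
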