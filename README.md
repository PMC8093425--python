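# precipdiv

Scale-explicit synthesis of precipitation-manipulation experiments on plant
diversity.

Field experiments that add or remove rainfall disagree about how plant
diversity responds, partly because they are compared at different spatial
grains, with different manipulation magnitudes, in different climates.
`precipdiv` is a pipeline for synthesising such experiments without blurring
those distinctions.  It is aimed at community ecologists and
meta-analysts working with plot-level species-abundance data from replicated
designs.

## What it computes

For every treatment in every experiment, diversity is summarised at three
scales:

* **local (α)** — per-plot species richness *S*, total cover, and the
  effective number of species `S_PIE = 1 / Σ p_i²` (inverse Simpson
  concentration, which weights common species), averaged over replicate
  plots;
* **site (γ)** — richness of the pooled replicate set rarefied to *n* = 3
  plots (analytic sample-based rarefaction plus a 1000-iteration bootstrap
  mean), and S_PIE of the pooled composition;
* **turnover (β)** — the site/local ratio (Whittaker's β for *S*),
  capturing plot-to-plot compositional heterogeneity.

Treatment effects are expressed as log response ratios,
`LRR = ln(treatment) − ln(control)`, per block at the local and turnover
scales and per experiment at the site scale.  The LRRs are then modelled
with hierarchical linear mixed models (random intercepts for study,
site-in-study, block-in-site) against the manipulation magnitude ΔP (% of
mean annual precipitation), background climate (MAP or PET), experiment
duration and the ΔP × climate interaction, with 2-SD covariate scaling,
AICc model selection, parametric-bootstrap 95% CIs and conditional R².
Robustness checks cover quadratic ΔP terms, direction-of-manipulation
interactions, √n-weighted refits, life-history (monocarpic vs polycarpic
dominants) analyses and study-level scale-dependence screens.

A synthetic-data generator produces study-shaped datasets (23 studies, 72
experiments, blocked designs) with known ground-truth effects on density,
evenness and turnover, so every estimator in the pipeline can be validated
against truth.  See `docs/methods.md` for the full model description.

## Worked example

```bash
# simulate a study-shaped dataset with known truth
precipdiv simulate --seed 4 --out sim/
# validate it
precipdiv validate --community sim/community.csv --meta sim/meta.csv
# diversity profiles, effect sizes, and the main model for local richness
precipdiv effects --community sim/community.csv --meta sim/meta.csv \
    --n-boot 1000 --seed 1 --out effects.csv
precipdiv fit --effects effects.csv --response S:local --climate MAP \
    --n-boot 1000 --seed 2 --out fit.json
```

The final command prints

```
best model for S:local: delta_P_s (AICc -525.95)
```

and writes `fit.json` with the REML coefficients and bootstrap CIs.  For
this seed the fitted ΔP slope (per 2 SD of ΔP) is 0.124 with 95% CI
[0.088, 0.157]: local species richness rises with experimentally added
precipitation and falls under drought, the direction the generator injects
(`beta_density = 0.3`).  The CI excluding zero is the significance rule
used throughout.  `conditional_r2` ≈ 0.32 says about a third of the LRR
variance is captured by fixed plus random effects, `marginal_r2` ≈ 0.16 by
the fixed effects alone.

The same workflow applies unchanged to real compiled data in the documented
CSV layout (`precipdiv validate --help` shows the dialect option for
arbitrary column headers).

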