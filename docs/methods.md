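# Methods

`precipdiv` synthesises replicated precipitation-manipulation experiments on
plant communities into scale-explicit diversity effect sizes and models them
hierarchically.  This note records the statistical model, the choices behind
it, and what the synthetic-data tests do and do not demonstrate.

## Response variables and spatial scales

For every treatment (a manipulation arm or its control) within an
experiment, four response families are computed from the plot-level species
abundances (percent cover, biomass, or point-intercept hits; units are never
converted — they cancel in the log response ratios):

1. **Total cover** — the summed abundance per plot, averaged over plots.
2. **Species richness S** at two scales: *local* — the mean number of
   species per plot — and *site* — the richness of the pooled replicate set,
   rarefied down to a common depth of `n_ref = 3` plots so that treatments
   with different replication are comparable.  Sample-based rarefaction uses
   the analytic hypergeometric form
   `E[S_n] = sum_i (1 - C(N - m_i, n) / C(N, n))`,
   where `m_i` is the number of plots occupied by species *i*.  The
   site-scale richness entering turnover ratios is additionally averaged
   over `n_boot = 1000` with-replacement resamples of the plot list
   (bootstrap mean); the plain analytic value is reported alongside for
   transparency, and serves as the oracle in tests (an exhaustive mean over
   all `C(N, n)` subsets).
3. **S_PIE**, the effective number of species of the probability of
   interspecific encounter: `S_PIE = 1 / sum_i p_i^2` with `p_i` the
   relative abundances.  No finite-sample correction is applied: cover and
   biomass data carry no individual count to correct by, and the
   inverse-Simpson form is exactly the index used downstream.  Local scale
   averages per-plot S_PIE; site scale evaluates S_PIE on the pooled
   composition.
4. **Turnover (beta) ratios** — site / local for both S and S_PIE.  For S
   this is Whittaker's beta diversity.  `beta_S >= 1` always; `beta_SPIE`
   can drop below 1 when unequal plot totals let one dominant plot swamp
   the pooled composition (a constructed counterexample is kept in the test
   suite).

Treatments with fewer than `n_ref` plots get missing site-scale values —
richness is only ever rarefied downward, never extrapolated.  Empty plots
propagate as missing values, not exceptions.

## Effect sizes

The effect-size currency is the log response ratio
`LRR = ln(treatment) - ln(control)`; negative values mean the manipulation
decreased the response.  Granularity follows the blocked designs:

* **local and turnover scales** — one row per block × non-control
  treatment.  Local LRRs contrast within-block means of the plot metrics;
  the turnover LRR contrasts each arm's beta ratio built from the arm's
  treatment-level site metric divided by the block's local mean.  Studies
  without blocking are treated as a single block.
* **site scale** — one row per experiment × metric, contrasting the
  treatment-level gamma metrics (bootstrap-mean rarefied richness for S,
  pooled S_PIE).

Rows with a zero or missing metric in either arm are dropped with a logged
warning; no offset constant is ever added, since offsets distort small
values.  Multiple treatments in one experiment share the control arm; the
hierarchical random structure absorbs the induced dependence.

## Hierarchical meta-regression

LRRs are modelled with Gaussian linear mixed models: nested random
intercepts for study, site-in-study and — at local/turnover scales —
block-in-site, with fixed effects drawn from the scaled manipulation
magnitude (delta_P, a signed percent of MAP), background climate (MAP, or
PET substituted), experiment duration, and the delta_P × climate
interaction.  Implementation uses `statsmodels` `MixedLM` (variance
components for the nested factors).  Details:

* **Covariate scaling.**  All continuous covariates are centred and divided
  by two standard deviations, putting their slopes on a scale comparable to
  binary contrasts.  The scaling record is retained for back-transformation.
* **Identifiability guard.**  A block variance component whose every level
  contains a single row is aliased with the residual variance and is
  dropped from the random structure (the same restriction lme4 enforces).
  With one treatment per experiment this is the usual case; the block term
  activates when treatments share control blocks.
* **Estimation.**  Maximum likelihood for every fit entering an AICc
  comparison; the selected specification is refit by REML for reported
  estimates.  Optimizer: L-BFGS with Powell and CG fallbacks;
  non-convergence is flagged, never silently dropped.
* **Model selection.**  Candidates form a nested ladder —
  `{1} ⊂ {dP} ⊂ {dP, climate} ⊂ {dP, climate, dP×climate} ⊂ {…, duration}` —
  plus configured robustness variants (PET for MAP; quadratic dP;
  dP × direction).  All candidates are fit on the identical row set and
  ranked by `AICc = -2l + 2k + 2k(k+1)/(n-k-1)`, where *k* counts fixed
  effects, every variance component and the residual variance.  Ties go to
  the model with fewer parameters.
* **Pairwise robustness comparisons** (`quadratic_test`,
  `direction_interaction_test`) retain the simpler model unless the
  extension improves AICc by more than 2 units — the conventional evidence
  threshold below which two models have comparable support.  A raw
  minimum-AICc rule would prefer a one-parameter extension with the
  irreducible ~14% chance implied by `P(chi2_1 > 2)`, which is noise, not
  evidence, for a yes/no robustness conclusion.
* **Uncertainty.**  Parametric bootstrap (default 1000 iterations):
  simulate the response from the fitted model respecting the nested random
  structure, refit, take 2.5/97.5 percentiles.  Refits that land on the
  variance boundary are legitimate draws and are kept; only numerically
  failed refits are discarded (warned above 10%).  An effect is significant
  when its 95% interval excludes zero; degrees-of-freedom p-values are
  deliberately not computed.
* **Variance explained.**  Marginal/conditional R² by variance partition:
  `R2_m = var(Xb) / (var(Xb) + sum(var_random) + var_resid)`, conditional
  adds the random variances to the numerator.

## Life history and diagnostics

The dominant species of each site is the one with the highest mean control
abundance at the endpoint (ties broken lexicographically and logged; the
control arm is used because treatment arms are perturbed).  Whether the
dominant is monocarpic (annual/biennial) versus polycarpic (perennial) is
regressed on climate with a maximum-likelihood random-intercept logistic
model — the study-level intercept is integrated out by 31-node
Gauss-Hermite quadrature, and the reported chi-square is the likelihood
ratio of the climate term (1 df).  This fitter is written in-package and is
cross-checked against `lme4::glmer` in development; a tiny L2 penalty
(1e-4) keeps separated data finite, with a separation flag above |slope| =
15.  Group differences in effect sizes between monocarp- and
polycarp-dominated systems use mixed models with study as the random term
and a parametric-bootstrap CI on the group contrast.

Scale-dependence screening follows the co-dependence logic of study-level
artefact checks: per-study means and variances of each effect size are
correlated with sample size and plot size, moderators are correlated with
those design variables (|r| >= 0.5 flags), and leave-one-out refits of the
`LRR ~ dP` model flag studies whose removal flips a slope's sign.  A
sensitivity refit weights each row's residual precision by the square root
of its sample size; because `MixedLM` carries no per-row residual weights,
this path uses an in-package marginal-likelihood fitter (profiled fixed
effects, log-SD parameterization, Nelder-Mead; equal weights reproduce the
`MixedLM` estimates to ~1e-3 in tests).

## Synthetic data generator

The generator emulates the structure of the compiled synthesis the
pipeline targets: 23 studies contributing 72 experiments (allocated as
evenly as possible), 3–10 blocks per experiment pairing one treatment and
one control plot (~460 block-level effect sizes), background MAP uniform on
225–1574 mm a⁻¹, manipulations up to ±80% of MAP (|delta_P| >= 5%),
durations of 1–15 years, plot sizes log-uniform on 0.08–2.5 m².  Effects
are injected on three axes:

* **density** — treatment plot intensity is `lambda_0 * exp(eta)` with
  `eta = beta_density * dP_s + beta_interaction * dP_s * MAP_s + u_study +
  u_site + u_block` and per-plot log-normal noise; plot totals are Poisson.
  Scaling inside the generator: `dP_s = delta_P / 100`, `MAP_s` mapped to
  ±1 at the MAP range ends.
* **evenness** — the treatment arm samples a species-abundance
  distribution whose shape parameter is re-calibrated by bisection (fixed
  lognormal z-scores, tolerance 0.1% relative) so the expected S_PIE
  log-ratio equals `beta_evenness * dP_s`.  Defaults: lognormal SAD,
  sigma = 1, 40-species pool, 100 individuals per control plot.
* **turnover** — an `aggregation` knob switches plot filling from
  multinomial to Dirichlet-multinomial with concentration
  `p / aggregation`, raising plot-to-plot heterogeneity with one parameter.

Counts are emitted as percent cover at 0.5% per individual.  Ground truth
per experiment records the injected density LRR, the calibrated S_PIE LRR,
and the expected local-richness LRR from the closed-form absence
probabilities (`exp(-lambda p_i)` under multinomial filling, the
beta-binomial form under aggregation).  Default effect sizes
(`beta_density = 0.3`, `beta_evenness = 0.15`, `beta_interaction = -0.2` —
responses strongest at dry sites, random-effect SDs 0.1 and residual 0.2
on the LRR scale) are conventional magnitudes for this literature, chosen
once.  The probability that a site's dominant is monocarpic rises with PET
(logit slope 1.5 by default), so the life-history analyses have signal.

A second generator draws block-level LRRs directly from the hierarchical
linear model (`lrr = X beta + u_study + u_site + u_block + eps`, covariates
pre-scaled), giving exact truth for inference tests.

**What the generator does not emulate:** real SADs and their spatial
autocorrelation, temporal dynamics (only a single endpoint exists),
observation error in cover estimation, species-specific drought responses,
seed-bank processes, or unbalanced/missing designs beyond unequal block
counts.  Passing tests therefore demonstrate that the estimators recover
known effects under the stated sampling model, not that the model captures
every feature of field data.

## Simulation sizes used by the test suite

Statistical checks run at sizes chosen to give tight binomial tolerances on
a single CPU: parameter recovery at the full design shape (23 studies,
69 experiments, 483 block rows, 100 replicates; each fixed effect within
±2 SE of truth in ≥90/100 — the per-coefficient reading, since four
jointly-tested coefficients at exact 95.4% marginal calibration cannot
reach a 90% joint rate); bootstrap coverage at 100 datasets × 100 refits
on a 12-study design (band 95% ± 5pp); selection consistency at 100
replicates; life-history type-I error at 200 replicates (band 1–10%).

## Known limitations

* The turnover-scale LRR construction (arm-level gamma over block-level
  alpha) is one defensible reading of block-granular turnover effect
  sizes; alternatives (e.g. experiment-level turnover only) would yield 72
  rather than ~460 rows at that scale.
* AICc counts variance components as free parameters even when an estimate
  sits on the zero boundary, which slightly penalises the hierarchical
  specs in small samples.
* The parametric bootstrap conditions on the estimated variance
  components; with very few clusters its intervals can be mildly
  anti-conservative (observed coverage 93/100 at the test design).
* `select_model` assumes every candidate is fit to the identical row set;
  rows missing any covariate used anywhere in the ladder are excluded
  globally before fitting.
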