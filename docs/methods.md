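# Methods

This note documents the models, defaults and numerical choices behind
`overyield`: what each stage computes, what the synthetic-experiment
generator does and does not emulate, and where the design was genuinely
open.

## Overyielding metrics

All metrics compare a species' observed productivity in mixture, `O_i`,
with its expectation under the null of no diversity effect,
`E_i = M_i * p_i`, where `M_i` is the mean productivity over the
replicate monoculture plots of that species at the same site *and the
same year* (strict same-year matching; gaps are reported, never
interpolated) and `p_i` is the sown or planted proportion.

* **Species lnRR** `= ln(O_i / E_i)`. Equivalent forms used as test
  oracles: `ln(RY_i / p_i)` with relative yield `RY_i = O_i / M_i`, and
  `exp(lnRR) − 1 = D_i`, the proportional deviation.
* **Community lnRR** `= ln(ΣO_i / ΣE_i) = ln(1 + D_T)`. Positive values
  mean community overyielding; the sign always agrees with the net
  biodiversity effect `ΔY = ΣO − ΣE`.
* **Additive partition**: with `ΔRY_i = O_i/M_i − p_i` and `N` species,
  `CE = N · mean(ΔRY) · mean(M)` and `SE = N · cov(ΔRY, M)` using the
  population (divide-by-N) covariance, so `NE = CE + SE = ΔY` holds as
  an exact floating-point identity rather than only in expectation.
  A sample (N−1) covariance would break the identity.
* **PO**: in communities with community lnRR > 0, the fraction of sown
  species with positive lnRR. The denominator is sown richness, so
  species whose lnRR is undefined (failed establishment, missing
  monoculture) count as non-overyielding. Groups: 0 < PO < 0.5,
  0.5 ≤ PO < 1, PO = 1.
* **CO_max**: `(O_imax − E_imax) / ΔY` for the species with the highest
  lnRR; per-species contributions `(O_i − E_i)/ΔY` always sum to 1.
  CO_max > 1 means the top species overcompensates underyielding
  elsewhere. Ties on lnRR are broken by larger `|O − E|`, then by input
  order (species id in the table driver); ties are logged.

**Undefined values and filtering.** lnRR diverges when `O_i` or `M_i`
approaches zero. The pipeline handles this in two logged stages:
(1) rows with non-positive `O_i` or `M_i`, or with no same-year
monoculture, are dropped with reason codes; (2) the remaining finite
species lnRRs are filtered two-tailed at the 0.5 and 99.5 percentiles,
pooled per system and measurement kind across sites (the pooling scope
is configurable; pooled is the default).

## Productivity kinds and the year window

Grassland productivity is annual peak aboveground biomass (g m⁻²).
Forest productivity uses annual basal-area increment, derived from
accumulated basal area by first differences; measurement gaps longer
than one year are annualized (divided by the gap), so the derived kind
is always "per year". Negative increments (mortality outpacing
growth) are retained at the I/O level with warnings and excluded later
by the lnRR domain rules. Analyses keep grassland years 1–10 and
forest years 3–13 (the first two forest years are dropped because
re-planting disturbs them).

## Traits: imputation, reliability, strategy axes

Six economics-spectrum traits are used: SLA (mm² mg⁻¹), LNC (mg g⁻¹),
LDMC (%), SRL (m g⁻¹), RNC (mg g⁻¹), RTD (g cm⁻³). All trait work is
on the log10 scale.

Missing cells are imputed by iterative ensemble-of-trees imputation
(scikit-learn's `IterativeImputer` with extremely-randomized trees — a
missForest-style algorithm), with an iterative ridge-regression
fallback. Only species with at least one measured trait are imputed;
others are excluded and reported. Phylogenetic information can be
added as the leading principal-coordinate eigenvectors of the
patristic distance matrix (default 10), appended as numeric covariates
to the feature block; the construction is isolated behind
`phylo_eigenvectors` so an alternative encoding can be substituted.

Reliability is assessed by mask-and-recover NRMSE: repeatedly mask a
fraction of the *measured* cells (default 10%, 10 repeats), re-impute,
and score per trait `RMSE(true, imputed) / range(measured)` on the
log10 scale. The repeats use a smaller forest (30 trees, 5
iterations) than a one-off imputation (100 trees, 10 iterations) to
keep the cross-validation loop affordable; both are deterministic
given the seed.

Strategy axes are the first two components of a PCA on the
standardized log10 traits (correlation-matrix PCA — the traits mix
units, so standardization is mandatory and is declared rather than
implicit). Scores are rescaled to unit variance so they enter the
trend models as comparable, unitless regressors. Each axis is
sign-oriented so a declared acquisitive marker trait loads positively
(defaults: SLA then LNC for grassland runs; LNC then SRL for forest
runs); orientation changes only signs, never magnitudes, and resolves
the inherent sign ambiguity of PCA axes.

## Temporal-trend models

Species-level model (per system): species lnRR on `PC1`, `PC2`,
`log2(SR)`, `ln(year)` and the interactions `PC × SR`, `PC × year`,
`SR × year`. Random structure: an intercept per species-in-plot
(SP_PlotID), an intercept per site, and site slopes for richness,
traits and year; residuals are AR(1)-correlated within each
species-in-plot series (`corr = phi^|Δyear|`, handling gapped years)
and independent across series. Community-level model: a community
response on `log2(SR) * ln(year)` with plot and site intercepts, site
slopes for richness and year, and AR(1) within plot. Transforms are
fixed: richness log2, year natural log, biomass responses log10; the
PC scores are already unit-variance composites of log10 traits and
enter untransformed (the log10 transform happens upstream of the PCA —
applying it twice would be wrong).

Estimation is REML via a purpose-built engine (`overyield.lmm`):
because every random term nests in the site, the marginal covariance
is block-diagonal by site; within a block the AR(1) Cholesky is exact
quasi-differencing (the process is Markov) and the random effects
enter through the Woodbury identity, so each objective evaluation
costs a few small q×q factorizations. Variance components are
profiled on the residual variance and optimized on the log scale with
L-BFGS-B; the AR(1) parameter is constrained to [0, 1) via a tanh
transform (positive temporal autocorrelation). statsmodels' MixedLM
covers the random effects but offers no residual correlation
structure, which is essential here; R's `nlme::lme` with `corCAR1`
fits the same family and serves as an independent oracle in the test
suite, reproducing fixed effects, the AR(1) parameter and the REML
log-likelihood on a shared fixture.

Inference: every fixed term is single-df, so F = t²; P values are
one-sided F tests. Denominator degrees of freedom use a numerical
Satterthwaite approximation (finite-difference gradient of each
coefficient's variance with respect to the variance parameters,
weighted by the inverse REML information), with a fast
containment-style count (observations − finest-grouping levels − rank)
as an alternative for repeated refits. Observations are unweighted.

If the full random structure fails to converge, a documented ladder
simplifies it — drop site trait slopes, then all site slopes, then
AR(1), then intercepts only — logging each step; single-site inputs
drop site terms automatically.

## The synthetic-experiment generator

The generator emulates the structure of multi-site grassland and
forest diversity experiments with known ground truth, so every claim
the tests make is a parameter-recovery or calibration statement.

* **Species pool.** Each species has a latent acquisitiveness
  `g ~ N(0,1)` and an independent nutrient-economy axis `h ~ N(0,1)`.
  log10 traits are linear in (g, h) plus independent noise with unit
  total variance; the g loadings follow the fast–slow sign pattern
  (SLA +0.88, SRL +0.85, LDMC −0.85, RTD −0.85, LNC +0.35, RNC +0.30)
  and h loads on the nitrogen traits (LNC 0.80, RNC 0.85). This gives
  a strongly integrated structural axis — PC1 explains ~55–60% of trait
  variance and correlates >0.9 with g at a 200-species pool — which is
  tighter than typical field PCAs (~40%); the generator is built for
  identifiability, and that is what passing recovery tests demonstrate.
  Missingness (default 15%, the share imputed in comparable trait
  compilations) is masked at random, never removing a species' last
  measured trait.
* **Monocultures.** `ln M_s(t) = ln(baseline) + mu_s + site +
  (delta0 + delta1 * g_s) ln t` with `delta1 = −0.05 < 0`: acquisitive
  monocultures decline faster (pathogen build-up). Baselines: ~300
  g m⁻² biomass (grassland), ~20 cm² yr⁻¹ increment (forest).
* **Overyielding surface.** A mixture species' expected lnRR is
  `beta = b0 + b1 g + b2 g ln t + b3 log2(SR) ln t` with defaults
  b0 = 0.10, b1 = 0.15 (acquisitive species overyield early),
  b2 = −0.05 (their advantage erodes; conservative species catch up),
  b3 = 0.03 (richness strengthens overyielding over time). Observed
  `ln O = ln p + ln M + beta + noise`.
* **Noise.** Stationary AR(1) in ln-space per plot–species series,
  marginal sd 0.20 and phi 0.5 — multiplicative log-normal noise
  matching the analysis model's assumptions, so recovery tests are
  well-posed. Site intercepts (sd 0.30) cancel in lnRR by design.
* **Designs.** Substitutive sowing `p = 1/SR`. Grassland default: 20
  sites, richness {1,2,4,8,16}, 2 plots per level, 2 replicate
  monocultures per species, 16 species per site, 10 years. Forest: 10
  sites, richness {1,2,4,8}, 13 years, basal area accumulated from
  increments; mortality events (configurable hazard) remove 20–60% of
  standing basal area, producing the decreasing accumulated series the
  increment derivation must flag. Forest mixture effects act on
  increments, not accumulated values, keeping accumulated series
  internally consistent.

**What the generator does not emulate:** individual plants or stems,
recruitment, climate forcing, unequal sowing designs (supported via
config but not defaulted), trait plasticity, or non-random trait
missingness. Passing tests therefore demonstrate correctness of the
accounting and estimation machinery under the stated stochastic model,
not robustness to every feature of real experimental data.

**A known property of lnRR data, and the calibration design.** Every
mixture observation of species *s* at a site is compared against the
same estimated monoculture reference, so lnRR errors inherit the
reference's error: correlated across all plots containing the species,
serially correlated over years, and — when the reference is the
arithmetic mean of two or more log-normal replicates — not exactly an
AR(1) Gaussian on the log scale. The trend model represents none of
this, and in null simulations under the realistic default design
(species recurring across plots, 2 replicate monocultures) the
nominal-5% trait × year test mis-calibrates in either direction
depending on the design's shape — we observed 8–10% rejection with
6-year series and 2–3% with 5-year series. Standard lnRR analyses
of real experiments share this property. The null-calibration
experiment in the acceptance suite therefore uses study conditions
under which the fitted model is exactly correctly specified: the
`disjoint_mixtures` layout (each species in at most one mixture plot
per site) with a single monoculture plot per species, so the reference
error is itself a Gaussian AR(1) absorbed exactly by the residual
model. Under those conditions the test is calibrated (observed ~5%
over 700 null refits). The calibration statement is thus about the
test machinery; the miscalibration under shared references is a
genuine property of lnRR-based inference, flagged here as a
limitation. The parameter-recovery experiments use the same
model-consistent conditions so the reported standard errors are an
honest yardstick; the default pipeline keeps the realistic shared
layout with 2 replicates.

Relatedly, on clean simulated data the 0.5/99.5 percentile filter
trims genuinely extreme overyielding rather than artifacts — the
log-normal generator never produces the near-zero observations the
filter exists to guard against — and measurably attenuates trait × year
slopes (~10% at the default conditions). Recovery experiments
therefore disable it; pipeline runs on data with establishment
failures should keep it.

## Problem sizes

Default analysis sizes (20-site grassland, 10-site forest, 200-species
pool) run the full pipeline in a few minutes on one CPU. The
calibration experiment refits a reduced design (8 sites, 5 years,
28 species per site, disjoint mixtures, single monocultures,
containment df) 500 times; the reduced size is chosen so the whole
experiment stays in the minutes range while leaving enough replication
to see a 2-point deviation from the nominal 5% level.

## Limitations

* The engine fits diagonal random-effect covariances (independent
  intercepts and slopes); correlated random effects are not supported.
* AR(1) is the only residual correlation structure; phi is constrained
  non-negative.
* Plug-in REML F-tests are slightly anti-conservative at small numbers
  of sites and short series (no Kenward–Roger covariance adjustment);
  the Satterthwaite df correction does not remove all of this.
* The NRMSE assessment masks measured cells completely at random;
  structured missingness (whole trait blocks missing for clades) will
  look better in cross-validation than it deserves.
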