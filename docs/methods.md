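# Methods

## The model

`mrocc` fits a multi-region, multispecies occupancy model to camera-trap
detection histories from R independently sampled regions (forest areas, each
with its own camera array). The data are day counts `y[i,j,r]`: the number of
days species `i` was detected at site `j` of region `r`, out of `K[j,r]`
active camera-days. Three linked submodels share one latent structure:

1. **Membership / richness.** Each region's species list is padded to a fixed
   superpopulation of `M` rows (data augmentation); rows beyond the `n_r`
   detected species carry all-zero histories. A latent indicator
   `omega[i,r] ~ Bernoulli(Omega_r)` flags whether row `i` is a real member of
   region `r`'s community, and richness is the derived count
   `N_r = sum_i omega[i,r]`, so `E[N_r] = M * Omega_r`. The membership
   probability is modelled on the logit scale with region covariates:
   continent dummies (Afrotropics reference), sampled area, NDVI,
   precipitation CV, human density, settlement distance, forest cover, and
   patch radius of gyration.

2. **Occupancy.** Conditional on membership, site-level occupancy states are
   `z[i,j,r] ~ Bernoulli(psi[i,r] * omega[i,r])`, with
   `logit(psi[i,r]) = theta0 + theta . (hden, forest, psize, settl) +
   eps_psi[i,r]` and species-within-region random effects
   `eps_psi[i,r] ~ Normal(0, sigma_psi_r)`. Occupancy is assumed equal across
   sites within a region; there is no spatial field (site exchangeability).

3. **Detection.** `y[i,j,r] ~ Binomial(K[j,r], p[i,j,r] * z[i,j,r])`, with
   `logit(p) = alpha0 + alpha1 * CAM_TYPE + alpha2 * SETTL_site +
   eps_p[i,r]`, `eps_p[i,r] ~ Normal(0, sigma_p_r)`. `CAM_TYPE` is a 0/1
   dummy (fast-trigger camera = 0 reference, moderate = 1).

A species detected in two regions is treated as two independent inferential
units (independent `eps` in each region); species identity is used only for
reporting. All continuous covariates are standardized to mean 0, sample SD 1
(`n-1` denominator); region-level covariates are scaled across the R
regions, site-level settlement distance across all sites pooled over regions
so the shared detection coefficient has a single scale.

The displayed occupancy and detection equations admit two readings of their
intercepts ("theta0_ir", "alpha0_ir"): a species-by-region intercept or a
community intercept plus the species random effect. We implement the latter —
one community intercept per block with the species/region variation carried
entirely by `eps` — because the random-effect terms are what give the model
its partial pooling. Similarly, the random-effect SDs are region-specific
(`sigma_psi_r`, `sigma_p_r`), not species-specific.

## Priors

Slope coefficients: Normal(0, sd 1.5) — weakly informative on the logit
scale for standardized covariates. Intercepts: Logistic(0, 1), i.e. uniform
on the probability scale. Random-effect SDs: Uniform(0, 5), independent per
region. All overridable through `PriorSpec` (YAML-serializable).

## Sampler

A Metropolis-within-Gibbs sweep per iteration:

1. `omega` is drawn from its full conditional with `z` marginalized site by
   site (partially collapsed). Without collapsing, an augmented row with
   `z = 0` everywhere could never re-enter the community when `psi` is high:
   collapsing removes that near-reducibility.
2. `z` is drawn from its full conditional given the fresh `omega`:
   1 wherever `y >= 1`, 0 wherever `omega = 0`, else
   `psi q^K / (psi q^K + 1 - psi)` with `q = 1 - p`.
3. Continuous blocks update by univariate adaptive random-walk Metropolis:
   the three coefficient vectors component-wise, the `eps` arrays
   element-wise (each element touches only its own species' likelihood, so
   all R x M proposals are evaluated and accepted in parallel), and the SDs
   on the log scale with the Jacobian correction, rejecting proposals
   outside the prior support.
4. A joint rescaling move per region and block: propose
   `(sigma_r, eps_r) -> (c sigma_r, c eps_r)` with `log c` a Gaussian step.
   The univariate walks cross the funnel between a random-effect SD and its
   effects very slowly (worst-case ESS in the single digits per thousand
   draws without this move); rescaling moves along the funnel axis directly.
   The acceptance ratio is the likelihood change plus `log c` (the residual
   of the prior term `-M log c` against the `(M+1) log c` Jacobian).

Proposal scales adapt by Robbins–Monro (`log s += t^-0.6 (a - 0.44)`) toward
a 0.44 univariate acceptance rate during burn-in only; the post-burn-in
kernel is fixed, so retained draws come from a valid time-homogeneous chain.
Initial values: coefficients 0, SDs 1, `omega = 1` for detected rows and
Bernoulli(0.5) for augmented rows, `z` the element-wise max of the
detection-implied state and Bernoulli(0.5). If the random initialization has
zero posterior density (possible when parameters are pinned near a boundary
in fixed-parameter runs), it falls back to the detection-implied minimal
state; a still-impossible state raises.

Presets: `desk` (3 chains x 15,000, burn-in 5,000) for interactive use;
`paper` (3 chains, burn-in 100,000, 400,000 retained post-burn-in draws,
thin 1) matching a full-study configuration; `recovery` (1 chain x 4,000,
burn-in 1,500) for replicated simulation studies. Convergence is declared at
R-hat <= 1.01 for monitored parameters; the CLI treats R-hat > 1.1 as an
error unless `--allow-unconverged`.

## Diagnostics

R-hat is the classic Gelman–Rubin potential scale reduction factor,
split-chain by default; the unsplit multi-chain variant is available
(`split=False`) and is the documented form for the two-chain hand-check
(identical chains `[1,2,3,4]` give sqrt(0.75) ~ 0.866, not 1, at this tiny
length). Effective sample size uses the classic autocorrelation-sum
estimator with Geyer's initial-positive-sequence truncation. Constant chains
return NaN (undefined) rather than raising.

## Synthetic data generator

`generate_study` draws from exactly the generative model above, so the
sampler can be validated by parameter recovery. Default design: R = 37
regions split near-evenly across the three continents, 55 sites per region,
30-day windows, M_true = 55 — the scale of a global tropical camera-trap
compilation (~2,000 sites, ~60,000 camera-days). Region covariates are drawn
uniformly (log-uniformly for the right-skewed human density and forest
cover) within realistic published ranges, e.g. human density
0.05–400.18 people/km2 and patch gyration 18.58–396.03 m. Default generating
parameters echo reported effect magnitudes: richness intercept 0 (so an
average community of M/2 species), Neotropics effect −0.29, human-density
effect −0.15, occupancy intercept −1 with forest +0.18 and patch size
+0.42, detection intercept −3.5 (daily detection ~0.03), moderate-trigger
penalty −0.3, and random-effect SDs 0.75.

Site settlement distances are log-normal jitter (sd 0.3) around the region
mean; trigger classes mix 50/50 within regions. `M_true` is deliberately
distinct from the fitted `M`, so tests can leave augmentation headroom
(fit `M = 55` over `M_true = 40`) or stress the boundary. All latents are
recorded before the detected-species filter, so truth exists for
never-detected species. One seeded generator stream per dataset makes output
a pure function of (design, params, covariates, seed).

What the generator does *not* emulate — and hence what passing recovery
tests cannot show about field data: spatially correlated occupancy,
unmodelled detection heterogeneity (behaviour, abundance), species shared
across regions with correlated effects, misidentification, and camera
failures within the window. An optional log10 transform for skewed
covariates is provided but off by default, matching a pipeline that
standardizes raw values.

## Derived quantities

Effects are classified from equal-tailed credible intervals: significant if
the 90% interval excludes 0, weak if only the 50% interval does. Prediction
curves hold other covariates at the reference profile (standardized 0,
Afrotropics, fast camera) and set species random effects to zero — the
community-median species; an integrate-over-effects option
(`integrate_random_effects=True`) averages the inverse logit over
`eps ~ Normal(0, sigma)` instead, which is systematically nearer 0.5. The
marginal human-density effect solves, at the posterior-median coefficients,
for the raw-scale density increase whose expected richness equals
`(1 - d)` times the reference value (closed form through the logit link; a
bisection cross-check is kept in the test suite); it is undefined (NaN) when
the human-density coefficient is zero or positive.

## Landscape metrics

Forest cover is the cell count times cell area (hectares). The radius of
gyration of a patch is the mean Euclidean distance from each cell centre to
the patch centroid (the mean of cell centres); the regional covariate is the
unweighted mean over patches — the literal reading of "averaged over all
patches" — with an area-weighted option. Patches are connected components
under 8-neighbour adjacency by default (the common landscape-metrics
convention), switchable to 4. Gyration values scale with the source raster's
resolution, so absolute published values are only reproducible from the
same raster.

## Auxiliary statistics

Moran's I uses row-standardized inverse great-circle-distance weights
between region centroids by default (binary k-nearest-neighbour available) —
the weight scheme must be stated because I is not invariant to it — with a
one-sided permutation p-value (9,999 seeded permutations). Welch's t is the
unequal-variance two-sample test with Welch–Satterthwaite df. Collinearity
screens: pairwise Pearson correlation flagged at |r| > 0.6 and VIF flagged
at >= 4, with perfect collinearity reported as infinite VIF rather than an
error.

## Numerical choices

- All probability arithmetic runs on the logit scale via `log_expit`;
  `log(1-p)` is computed as `log_expit(x) - x` to avoid cancellation.
- Padded sites (regions with fewer sites than the widest region) carry
  `K = 0` and a mask, contributing exactly zero to every likelihood term.
- The binomial coefficient sum is constant across iterations (nonzero only
  where `y > 0`, which forces `z = 1`) and is added once to the recorded
  log-posterior.
- Impossible configurations (`y >= 1` with `z = 0`) yield -inf
  log-likelihood, not an exception.
- Quantiles use numpy's linear interpolation; richness medians are rounded
  to whole species only in reporting tables.

## Problem sizes used in validation

The exact-oracle check runs 100,000 retained draws on a 1-region instance
(M = 3, J = 2, K = 2) against full enumeration of all 512 (omega, z)
states (total variation < 0.02). The recovery study uses 25 replicates of
R = 20, J = 40, K = 30, M_true = 40 fitted with M = 55 under the `recovery`
preset — sizes chosen so the whole study completes in minutes while leaving
the per-replicate posterior well resolved. The end-to-end pipeline check in
`scripts/acceptance.py` fits an 8-region, 30-site study with 2 chains x
4,000 iterations.

## Known limitations

- No multi-season (dynamic) occupancy, species traits, or spatial random
  fields.
- Cross-region species identity is ignored by the model (by design).
- The permutation Moran test loops in Python; it is meant for R ~ tens of
  regions, not thousands of units.
- The sampler is single-machine and CPU-bound; the `paper` preset takes
  hours at full study scale.
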