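# mrocc — multi-region community occupancy modelling

`mrocc` estimates **species richness** and **community occupancy** jointly
across many camera-trap survey regions, under imperfect detection. It is
aimed at community ecologists analysing multi-area camera-trap compilations
(tens of forest regions, tens of cameras each, ~30-day windows) who want to
relate the size and distribution of partially observed mammal communities to
landscape covariates — human density, forest cover, fragmentation, distance
to settlements — without pretending every resident species was detected.

## The model

For region *r* with detection array `y[i,j,r]` (days species *i* was seen at
site *j*, out of `K[j,r]` camera-days), the species list is padded to a
superpopulation of *M* rows (data augmentation) and three logit-linear
submodels share the latent structure:

    omega_ir ~ Bernoulli(Omega_r)                     membership
    logit(Omega_r) = beta0 + beta1 NEO_r + beta2 INDO_r + beta3 AREA_r
                   + beta4 NDVI_r + beta5 CVPREC_r + beta6 HDEN_r
                   + beta7 SETTL_r + beta8 FOREST_r + beta9 PSIZE_r

    z_ijr ~ Bernoulli(psi_ir * omega_ir)              occupancy
    logit(psi_ir) = theta0 + theta1 HDEN_r + theta2 FOREST_r
                  + theta3 PSIZE_r + theta4 SETTL_r + eps_psi_ir,
    eps_psi_ir ~ Normal(0, sigma_psi_r)

    y_ijr ~ Binomial(K_jr, p_ijr * z_ijr)             detection
    logit(p_ijr) = alpha0 + alpha1 CAM_TYPE_jr + alpha2 SETTL_jr + eps_p_ir,
    eps_p_ir ~ Normal(0, sigma_p_r)

Richness is the derived count `N_r = sum_i omega_ir`, with
`E[N_r] = M * Omega_r`. Inference is by a Metropolis-within-Gibbs sampler
(collapsed membership updates, adaptive random-walk blocks, a joint
scale move for the random-effect SDs); see `docs/methods.md` for the full
account. The package also ships a synthetic-study generator with known
ground truth, landscape metrics (forest cover, patch radius of gyration) for
binary habitat grids, and the satellite statistics such an analysis uses
(Moran's I, Welch's t, Pearson/VIF collinearity screens).

## Worked example

Simulate a 20-region study from the default generating model (55 sites per
region would be the full default; here 40), fit it, and compare against the
known truth:

```python
from mrocc import generate_study, StudyDesign, fit, SamplerConfig
from mrocc.derived import effects_table, richness_table

data, truth = generate_study(StudyDesign(R=20, J=40, K=30, M_true=55), seed=42)
samples = fit(data, truth.covariates, M=55,
              config=SamplerConfig(n_chains=2, n_iter=6000, n_burnin=2000, seed=42))
print(richness_table(samples).head(6))
print(effects_table(samples).query("block == 'occupancy'"))
```

Output (about a minute on one CPU):

```
region_id  n_observed  N_median  N_mean  lo90  hi90
      R01          28        29   29.41  28.0  32.0
      R02          30        33   32.81  30.0  36.0
      R03          28        35   35.27  30.0  41.0
      R04          29        30   30.58  29.0  33.0
      R05          16        20   21.02  17.0  27.0
      R06          24        25   25.65  24.0  28.0

    block parameter  median   lo50  hi50   lo90  hi90   significance
occupancy      hden   0.054 -0.001 0.103 -0.084 0.176           none
occupancy forest_ha   0.229  0.181 0.276  0.102 0.345 significant_90
occupancy   psize_m   0.420  0.378 0.465  0.323 0.529 significant_90
occupancy   settl_m  -0.012 -0.063 0.038 -0.134 0.108           none
```

Reading it: the first table gives, per region, the observed species count
`n_observed` and the posterior median and 90% credible interval of true
richness `N` — the model adds the species it believes were present but never
photographed (true values here were 29, 31, 30, 30, 16, 26; the 90%
intervals cover 18 of the 20 regions). The second table shows standardized
community-occupancy effects with their credible intervals: the generating
values (forest +0.18, patch size +0.42) are recovered and correctly flagged
as significant — an effect is `significant_90` when its 90% interval
excludes zero, `weak_50` when only the 50% interval does.

The same pipeline runs from the shell:

```sh
mrocc simulate --out study/ --regions 20 --sites 40 --days 30 --seed 42
mrocc fit --out run/ --detections study/detections.csv \
    --region-covariates study/region_covariates.csv \
    --site-covariates study/site_covariates.csv --m 55 --seed 42
mrocc report run/
```

plus `mrocc metrics --grid forest.asc` for landscape metrics and
`mrocc screen-covariates region_covariates.csv` for the collinearity screen.

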