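# pedgxe

Variance-components analysis of quantitative traits in extended pedigrees
with **genotype-by-environment (GxE) interaction along a continuous
environmental gradient**, built for family studies of metabolic-syndrome
risk factors where the environment is a standardized socioeconomic score
(zSES) and the data carry both genetic (kinship) and shared-household
structure.

## The model

Each trait is decomposed into additive genetic, optional household, and
residual environmental components,

- model 1: sigma_p^2 = sigma_g^2 + sigma_e^2
- model 2: sigma_p^2 = sigma_g^2 + sigma_c^2 + sigma_e^2

with heritability h^2 = sigma_g^2 / sigma_p^2 and household share
c^2 = sigma_c^2 / sigma_p^2.  GxE interaction is modelled by letting the
component variances vary over the environment and the genetic (and
household) correlations decay with environmental distance:

    sigma_g^2(z) = exp(alpha_g + gamma_g * z)
    sigma_e^2(z) = exp(alpha_e + gamma_e * z)
    sigma_c^2(z) = exp(alpha_c + gamma_c * z)
    rho_g(z_i, z_j) = exp(-lambda_g * |z_i - z_j|)
    rho_c(z_i, z_j) = exp(-lambda_c * |z_i - z_j|)

There is no GxE when sigma_g^2 is homogeneous (gamma_g = 0) **and** the
genetic correlation is 1 across environments (lambda_g = 0); rejecting
either sub-hypothesis establishes GxE as covariance heterogeneity across
the environmental continuum.  The phenotypic covariance of a family block
is

    Omega_ij = K_ij * sqrt(sigma_g^2(z_i) sigma_g^2(z_j)) * rho_g(z_i, z_j)
             + H_ij * sqrt(sigma_c^2(z_i) sigma_c^2(z_j)) * rho_c(z_i, z_j)
             + 1[i = j] * sigma_e^2(z_i)

with K the additive relationship (2x kinship) matrix from the recursive
tabular method and H the same-household indicator.  Parameters are
estimated by maximum likelihood over independent family blocks, and
hypotheses are tested in a three-stage likelihood-ratio procedure with
boundary-aware null distributions (half-mixtures for variance components
and decay rates constrained at zero) and panel-wise Bonferroni adjustment.

A synthetic-data module generates study-scale datasets — 42 extended
families of ~1,100-1,500 individuals, household-clustered zSES, traits
drawn from the exact generative counterpart of the fitted covariance —
so every stage of the pipeline is testable without access to restricted
family data.

## Worked example

```python
from pedgxe import fit_ml, model1_spec, prepare_data, scenario_presets, simulate_dataset

scenario = scenario_presets(seed=11)["polygenic"]   # h^2 truth 0.45
ped, frame = simulate_dataset(scenario)
data = prepare_data(ped, frame)
fit = fit_ml(data, model1_spec(), seed=0)
h2, _ = fit.heritability()
print(f"h^2 = {h2:.3f} (SE {fit.h2_se(data):.3f})")
```

prints

```
h^2 = 0.401 (SE 0.049)
```

an estimate of the simulated heritability of 0.45 with the standard error
on the scale family studies of this size report (~0.05-0.07).  The
`examples/` directory walks through each capability: kinship and family
blocks (`01`), the study simulator (`02`), heritability fitting (`03`),
the full three-stage GxE screen with its table-shaped output (`04`), and
figure-ready variance-function grids (`05`).  A thin CLI mirrors the
library: `pedgxe simulate | preprocess | fit | run-panel | export`.

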