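# noxtrace

Nitrogen-isotope source apportionment of atmospheric NOx emissions.

Precipitation nitrate carries the nitrogen-isotope signature (δ¹⁵N, ‰ vs.
atmospheric N₂) of the NOx sources that produced it. Because coal combustion
(δ¹⁵N ≈ 13.7 ± 3.9‰) and soil microbial N cycling (δ¹⁵N ≈ −30.2 ± 6.7‰) sit at
opposite ends of the source range, δ¹⁵N of wet-deposited nitrate
(δ¹⁵N_w-NO₃⁻) can be inverted for the fractional contributions of fossil
(coal, vehicle exhaust) and non-fossil (biomass burning, microbial) NOx
sources — provided the isotope effect of atmospheric processing between the
initial NOx pool and precipitation nitrate is corrected for. `noxtrace`
implements that inference chain for atmospheric and biogeochemistry
researchers:

1. **Initial-NOx reconstruction.** δ¹⁵N of the initial NOx pool is a
   concentration-weighted mean of ambient NOx, HNO₃, and particulate-NO₃⁻
   δ¹⁵N values, with weights (C_NO₂/f_NO₂, C_HNO₃, C_p-NO₃⁻). The per-record
   offset ¹⁵Δ = δ¹⁵N_w-NO₃⁻ − δ¹⁵N_i-NOx is estimated under two data
   scenarios and pooled (mean of means; SDs combined in quadrature).
2. **Bayesian mixing model.** δ¹⁵N_w-NO₃⁻ observations are modelled as
   x ~ N(Σₖ fₖμₖ + ¹⁵Δ, Σₖ fₖ²σₖ² + σ_Δ² + σ_res²) with a Dirichlet(1,…,1)
   prior on the fraction simplex f and a half-normal prior on the residual
   SD. Sampling is adaptive random-walk Metropolis on the additive log-ratio
   transform of the simplex; four sources are used at urban sites, three
   (vehicle exhaust excluded) at non-urban sites.
3. **Regional budgets.** Urban/non-urban posterior fractions are combined
   with population weights, split into fossil and non-fossil shares, and
   converted into emission amounts via A_total = A_fossil/F_fossil and
   A_non-fossil = A_total − A_fossil, with Monte Carlo uncertainty
   propagation through truncated-normal inputs.
4. **Descriptive statistics.** One-way ANOVA across regions, Welch tests
   between urban and non-urban site means (significance at P < 0.1), and
   linear temporal trends with Pearson correlations and 95% confidence
   bands.

A synthetic-data module generates observation tables, forward-simulated
mixtures, and ambient-chemistry records with the statistical structure the
analysis assumes, so the whole chain is testable without any external data.

## Worked example

```python
from noxtrace import (FractionationEstimate, McmcSettings, MixtureSpec,
                      SourceSignature, fit_mixing_model,
                      generate_mixture_observations, pooled_offset,
                      propagate_uncertainty, summarize)

# 1. pool the two scenario estimates of the fractionation offset
offset = pooled_offset(FractionationEstimate(2.1, 1.7, "scenario1", 24),
                       FractionationEstimate(5.7, 3.2, "scenario2", 18))
print(f"offset: {offset.mean:.1f} +/- {offset.sd:.1f} permil")

# 2. fit the four-source mixing model to a forward-simulated urban mixture
sources = [SourceSignature("coal_combustion", 13.7, 3.9),
           SourceSignature("vehicle_exhaust", -4.0, 3.0),
           SourceSignature("biomass_burning", 1.0, 4.0),
           SourceSignature("microbial_N", -30.2, 6.7)]
spec = MixtureSpec((0.35, 0.25, 0.15, 0.25),
                   tuple(s.mean for s in sources), tuple(s.sd for s in sources),
                   offset_mean=offset.mean, offset_sd=offset.sd,
                   residual_sd=1.0, n_obs=200)
obs = generate_mixture_observations(spec, seed=42)
post = fit_mixing_model(obs, sources, offset, McmcSettings(seed=42))
print(summarize(post).round(3))

# 3. turn an inventory fossil amount and fossil share into a budget
budget = propagate_uncertainty(a_fossil=16.3, a_fossil_sd=7.1,
                               f_fossil=0.43, f_fossil_sd=0.05,
                               n_draws=10_000, seed=42)
print(f"A_total      = {budget.a_total:.1f} +/- {budget.a_total_sd:.1f} Mt/yr")
print(f"A_non_fossil = {budget.a_non_fossil:.1f} +/- {budget.a_non_fossil_sd:.1f} Mt/yr")
```

prints

```
offset: 3.9 +/- 1.8 permil
                  mean     sd  ci2.5  ci97.5
source                                      
coal_combustion  0.205  0.099   0.04   0.404
vehicle_exhaust  0.348  0.212   0.05   0.825
biomass_burning  0.265  0.170   0.02   0.576
microbial_N      0.182  0.063   0.05   0.290
A_total      = 37.9 +/- 16.9 Mt/yr
A_non_fossil = 21.6 +/- 10.6 Mt/yr
```

The pooled offset is 3.9 ± 1.8‰; the posterior means recover the generating
fractions (0.35, 0.25, 0.15, 0.25) within their credible intervals — with a
single isotope dimension and overlapping end-members the fractions are only
weakly identified, which the wide intervals report honestly; and a 16.3
Mt yr⁻¹ fossil inventory with a 43% fossil share implies 37.9 Mt yr⁻¹ total
and 21.6 Mt yr⁻¹ non-fossil NOx emissions.

## Command line

`noxtrace` exposes subcommands `simulate`, `reconstruct`, `mix`,
`aggregate`, `budget`, `stats`, and `pipeline`; the last runs the whole
chain from one YAML configuration (see `docs/example_config.yaml`) and
writes every intermediate table plus a manifest with all seeds, so a run is
reproducible from the manifest alone.

```sh
noxtrace budget --a-fossil 16.297 --f-fossil 0.43 --n-draws 10000 --seed 1
noxtrace pipeline --config docs/example_config.yaml --outdir out/
```

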