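# Methods

## Scope and model overview

`noxtrace` infers the fractional contributions of four NOx emission sources
— coal combustion (S1), vehicle exhausts (S2), biomass burning (S3), and
microbial N cycling in soils and wastes (S4) — from the nitrogen-isotope
composition of nitrate in precipitation (δ¹⁵N_w-NO₃⁻, ‰ vs. atmospheric N₂),
and converts those fractions into regional emission amounts. The chain has
four stages: fractionation-offset estimation, Bayesian mixing, regional
aggregation, and budgeting. All randomness flows from explicit integer
seeds; every stage is deterministic given its inputs and seed.

## Initial-NOx reconstruction and the fractionation offset

Wet-deposited nitrate integrates ambient NO₂ and its oxidation products
(HNO₃ and particulate NO₃⁻). The δ¹⁵N of the initial NOx pool is therefore
reconstructed as the concentration-weighted mean

    δ¹⁵N_i-NOx = (δ¹⁵N_NOx·C_NO₂/f_NO₂ + δ¹⁵N_HNO₃·C_HNO₃ + δ¹⁵N_p-NO₃·C_p-NO₃)
                 / (C_NO₂/f_NO₂ + C_HNO₃ + C_p-NO₃)

where f_NO₂ is the NO₂ fraction of NOx (global mean 0.64 ± 0.10 used when
site values are missing, with δ¹⁵N_NOx = −7.7 ± 2.9‰). The expression is a
convex combination: it is bounded by the component δ¹⁵N extremes and
invariant to a common rescaling of the three concentrations, so any single
consistent concentration unit may be used. Both properties are enforced by
property-based tests.

The net isotope effect of atmospheric processing is the per-record offset
¹⁵Δ = δ¹⁵N_w-NO₃⁻ − δ¹⁵N_i-NOx. It is estimated in two scenarios
(synchronous vs. non-synchronous ambient observations), each summarized as
mean ± sample SD, and pooled as the average of the two means. For the
pooled SD the package propagates the two scenario SDs in quadrature,
√(s₁² + s₂²)/2 — the standard rule for the mean of two independent
estimates. The half-range |m₂ − m₁|/2 gives a numerically similar value for
typical inputs and is a defensible alternative; quadrature was chosen as
the statistically conventional one. With scenario estimates 2.1 ± 1.7‰ and
5.7 ± 3.2‰ the pooled offset is 3.9 ± 1.8‰ either way (after rounding).

## Bayesian mixing model

Observations are replicate δ¹⁵N_w-NO₃⁻ values at one site (or stratum). The
likelihood treats each observation as a draw from the source mixture after
fractionation:

    x_i ~ Normal( Σₖ fₖ μₖ + Δ,  Σₖ fₖ² σₖ² + σ_Δ² + σ_res² )

with source signatures (μₖ, σₖ), pooled offset (Δ, σ_Δ), and a residual SD
σ_res absorbing replicate-level scatter that the signature and offset
variances do not explain. Priors: f ~ Dirichlet(1, …, 1) (uninformative on
the simplex) and σ_res ~ half-Normal(scale 5‰); the scale is configurable
and deliberately weak — typical posterior residual SDs in the test suite
are an order of magnitude below it.

Vehicle exhaust is excluded at non-urban sites (K = 3), where long-range
transport contributes little traffic NOx; all four sources are used at
urban sites (K = 4). The sampler additionally accepts K = 2 so that it can
be cross-checked against the exact algebraic inversion
f₁ = (x̄ − Δ − μ₂)/(μ₁ − μ₂).

**Sampler.** Random-walk Metropolis on the additive log-ratio (ALR)
transform of the simplex jointly with log σ_res, with the Dirichlet prior
carried into ALR space through its Jacobian (Σₖ log fₖ) and the half-normal
prior through the log-transform Jacobian. The proposal is an isotropic
normal whose scale adapts every 50 iterations during burn-in toward ~30%
acceptance (multiplicative update, clipped to [10⁻³, 10]) and is frozen
afterwards so the post-burn-in chain is a valid Markov chain. Because the
observation variance is common to all observations, the log-likelihood
depends on the data only through (n, Σx, Σx²); each step is O(K), which
keeps repeated-fit validation cheap.

Defaults: 4 chains × 10 000 iterations, 5 000 burn-in, thinning 2 — 10 000
retained draws. Convergence is monitored with the split-chain potential
scale reduction (R̂, via arviz) per fraction and for σ_res;
`check_convergence` flags parameters above a 1.05 threshold and requires at
least two chains.

**Permutation equivariance.** An ALR parameterization singles out a
reference coordinate, so a naive implementation would not commute with
reordering the source list. The model therefore sorts sources into a
canonical internal order (by mean, SD, name) before sampling and permutes
the posterior columns back, making fits exactly equivariant under input
permutations at fixed seed.

**Identifiability.** One isotope dimension cannot sharply resolve three or
four fractions; posteriors are honest about this through wide credible
intervals, and the package warns (rather than fails) when all source means
coincide. Validation therefore focuses on calibration: across 20 seeded
forward simulations per K (n = 200 observations each, source SDs at their
published coal/microbial values), nominal 95% intervals must cover the
generating fractions at a rate not statistically below 0.95, and the
two-source posterior mean must match the closed form within 0.03 in the
well-identified limit. These problem sizes were chosen to make the binomial
coverage test informative while keeping the full validation suite fast.

## Regional aggregation and budgets

Region-wide contribution of each source is the population-weighted mean of
its urban and non-urban fractions,

    F = f_urban·P_urban + f_non-urban·P_non-urban.

A literal product of all four factors is sometimes written for this
quantity, but it is dimensionally inconsistent with a relative contribution
and destroys closure (Σ_sources F = 1); the package treats that form as a
typographical artifact, implements the weighted sum, and keeps the product
available behind `literal_product=True` strictly for audit.

Fossil and non-fossil shares are F_fossil = F_S1 + F_S2 and F_non-fossil =
F_S3 + F_S4. Budgets follow from the inventory fossil amount:
A_total = A_fossil/F_fossil and A_non-fossil = A_total − A_fossil, which
satisfy A_non-fossil = A_total·(1 − F_fossil) identically. F_fossil = 0 is
rejected (an all-non-fossil regime, outside the identity's validity).

**Monte Carlo propagation.** Inputs are drawn from truncated normals
(amounts on [0, ∞), fractions on (0, 1]) or taken directly from posterior
draws when supplied; the identities are applied per draw and SDs of the
derived quantities reported. Central values are the deterministic budget,
so closure holds exactly both centrally and per draw. Default 10 000 draws;
the propagated SD of A_total is validated against a 10⁶-draw direct
simulation to within 2%. Note that A_total = A_fossil/F_fossil is
heavy-tailed in 1/F_fossil: when the fossil-share SD is large relative to
its mean (e.g. 0.43 ± 0.13), draws near the lower truncation bound inflate
the SD far beyond a first-order (delta-method) estimate. The package
reports the exact Monte Carlo SD of the draws it makes and leaves any
tail-trimming to the user, who can pass posterior fraction draws directly.

**Aggregation across regions.** A single cross-region non-fossil share can
be formed as an unweighted mean of regional shares or weighted by regional
emission totals; both are computed (`aggregate_regions`) because the choice
is a reporting convention, not a physical one. Year windows for averaging
are per-region configuration, since the appropriate inventory window
differs by region and data coverage.

## Synthetic data

The generator emulates the structure the inference assumes, not any real
archive:

- **Observation tables.** Per-stratum (region × site class) normal δ¹⁵N
  distributions with configurable mean/SD; stratum variance split between
  site means and within-site replicates (default 50/50); default 5
  replicates per site-year (replication per site-year is a free parameter
  of the design, so it is exposed rather than fixed). Default stratum
  moments and site counts follow the published urban/non-urban summaries
  for East Asia, Europe, and North America.
- **Mixtures.** Forward simulation of the mixing likelihood with known
  fractions, for parameter-recovery tests; with all variances zero the
  mass balance holds exactly.
- **Ambient records.** Log-normal concentrations (positivity), truncated
  normal f_NO₂ on (0, 1], normal isotope values.

What the generator does *not* emulate: spatial autocorrelation between
sites, seasonal sampling structure, digitization error in compiled
literature values, and non-normal within-site scatter. Passing tests
therefore demonstrate correctness of the inference machinery under its own
assumptions, not robustness of conclusions about any particular real
data set.

Only the coal-combustion (13.7 ± 3.9‰) and microbial (−30.2 ± 6.7‰)
end-member signatures ship as package constants; vehicle-exhaust and
biomass-burning signatures vary substantially between compilations and must
be supplied by the user (the test fixtures use synthetic values −4 ± 3‰ and
1 ± 4‰ chosen for separation and plausibility).

## Numerical choices and degenerate inputs

- Simplex draws are produced by a max-shifted softmax; every retained draw
  sums to 1 within 1e-9 and summaries renormalize nothing.
- Identical ANOVA groups can yield an epsilon-negative F statistic and NaN
  p-value in floating point; this is clamped to (F = 0, p = 1).
- Exactly identical source means trigger a non-identifiability warning, not
  an error; zero-variance strata, single-record scenarios (SD 0), and
  zero-SD Monte Carlo inputs (degenerate, SD-0 outputs) are all defined.
- Group-comparison tests operate on site means, not raw replicates, so
  heavily replicated sites do not dominate; urban-vs-non-urban contrasts
  use Welch's unequal-variance test rather than a pooled ANOVA contrast.
- Temporal trends are linear OLS fits with Pearson r and a pointwise 95%
  confidence band for the mean response; smoothed alternatives are out of
  scope.
- The pipeline derives stage seeds (synthesis, mixing, Monte Carlo) from
  one master seed via `numpy.random.SeedSequence.spawn`, and per-group MCMC
  seeds from the mixing-stage seed in sorted group order, so results are
  reproducible from the manifest alone and invariant to group iteration
  order.

## Known limitations

- A single isotope dimension bounds how sharply K ≥ 3 fractions can be
  resolved; results should be read as posterior distributions, not point
  apportionments.
- The model assumes source signatures and the fractionation offset are
  exchangeable across sites and years within a fit; systematic regional or
  temporal shifts in source δ¹⁵N alias into the fractions.
- Concentration-weighted (MixSIAR-style) extensions, a second isotope
  dimension (δ¹⁸O), and hierarchical pooling across sites are not
  implemented.
- Budget uncertainty inherits the heavy tail of the 1/F_fossil ratio, as
  discussed above.
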