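# Example pipeline configuration: fully synthetic, small enough to run in
# seconds.  Replace the synthetic block with `observations: {path: obs.tsv}`
# to analyse a real replicate table.
seed: 42
outdir: out

# End-member delta15N signatures (permil).  All four must be given: vehicle
# and biomass values vary between compilations, so the package ships no
# defaults for them; the values below are synthetic placeholders.
sources:
  coal_combustion: {mean: 13.7, sd: 3.9}
  vehicle_exhaust: {mean: -4.0, sd: 3.0}
  biomass_burning: {mean: 1.0, sd: 4.0}
  microbial_N: {mean: -30.2, sd: 6.7}

observations:
  synthetic:
    strata:
      - {region: East Asia, site_class: urban, mean_delta: 1.7, sd_delta: 5.4,
         n_sites: 3, replicates_per_site: 5, year_range: [2010, 2011]}
      - {region: East Asia, site_class: non-urban, mean_delta: 0.3,
         sd_delta: 3.1, n_sites: 3, replicates_per_site: 5,
         year_range: [2010, 2011]}

# Fixed pooled fractionation offset; alternatively supply
#   offset: {scenario1: {path: ambient1.tsv}, scenario2: {path: ambient2.tsv}}
# to recompute it from ambient tables carrying a d15n_wno3 column.
offset: {mean: 3.9, sd: 1.8}

mcmc: {n_iter: 4000, burn_in: 2000, thin: 2, n_chains: 2}
monte_carlo: {n_draws: 10000}
fit_mode: site_year          # or "stratum" to pool replicates per stratum

regions:
  East Asia:
    a_fossil: 16.3           # inventory fossil NOx amount, Mt/yr
    a_fossil_sd: 7.1
    p_urban: 0.55            # urban population share
    year_window: [2000, 2016]
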