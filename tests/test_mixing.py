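"""Bayesian mixing model: oracles, invariants, and diagnostics."""

import numpy as np
import pytest

from noxtrace import (
    FractionationEstimate,
    McmcSettings,
    MixtureSpec,
    PosteriorContributions,
    SourceSignature,
    check_convergence,
    closed_form_two_source,
    fit_mixing_model,
    generate_mixture_observations,
    summarize,
)
from noxtrace.mixing import ConvergenceUnavailableError, NonIdentifiabilityWarning

FAST = dict(n_iter=4000, burn_in=2000, thin=2, n_chains=2)
NO_OFFSET = FractionationEstimate(0.0, 0.0)


def test_symmetric_two_source_posterior_is_balanced():
    sources = [SourceSignature("lo", -10.0, 1.0), SourceSignature("hi", 10.0, 1.0)]
    post = fit_mixing_model(np.zeros(50), sources, NO_OFFSET,
                            McmcSettings(seed=1, **FAST))
    means = summarize(post)["mean"]
    assert means["lo"] == pytest.approx(0.5, abs=0.05)
    assert means["hi"] == pytest.approx(0.5, abs=0.05)


def test_end_member_limit_attributes_mass_to_matching_source(offset_pooled):
    sources = [SourceSignature("coal_combustion", 13.7, 0.5),
               SourceSignature("biomass_burning", 1.0, 0.5),
               SourceSignature("microbial_N", -30.2, 0.5)]
    rng = np.random.default_rng(0)
    obs = 13.7 + offset_pooled.mean + rng.normal(0, 0.3, size=100)
    post = fit_mixing_model(obs, sources, offset_pooled,
                            McmcSettings(seed=2, **FAST))
    assert summarize(post).loc["coal_combustion", "mean"] > 0.9


def test_credible_intervals_cover_generating_fractions(sources3, offset_pooled):
    fractions = (0.6, 0.3, 0.1)
    spec = MixtureSpec(
        fractions,
        tuple(s.mean for s in sources3),
        tuple(s.sd for s in sources3),
        offset_mean=offset_pooled.mean,
        offset_sd=offset_pooled.sd,
        residual_sd=1.0,
        n_obs=200,
    )
    obs = generate_mixture_observations(spec, seed=21)
    post = fit_mixing_model(obs, sources3, offset_pooled,
                            McmcSettings(seed=22, **FAST))
    summary = summarize(post)
    for source, f_true in zip(sources3, fractions):
        row = summary.loc[source.name]
        assert row["ci2.5"] <= f_true <= row["ci97.5"]


def test_two_source_closed_form_inversion():
    coal = SourceSignature("coal_combustion", 13.7, 3.9)
    microbial = SourceSignature("microbial_N", -30.2, 6.7)
    # hand arithmetic: (-8.15 - 3.9 + 30.2) / (13.7 + 30.2)
    assert closed_form_two_source(-8.15, coal, microbial, 3.9) == pytest.approx(
        0.413, abs=5e-4
    )
    lo, hi = SourceSignature("lo", -10, 1), SourceSignature("hi", 10, 1)
    assert closed_form_two_source(0.0, hi, lo) == 0.5
    assert closed_form_two_source(10.0 + 2.0, hi, lo, offset_mean=2.0) == 1.0
    assert closed_form_two_source(100.0, hi, lo) == 1.0  # clamped
    with pytest.raises(ZeroDivisionError):
        closed_form_two_source(0.0, hi, hi)


def test_posterior_mean_matches_two_source_oracle():
    # well-identified limit: small source SDs, many observations
    hi = SourceSignature("hi", 10.0, 0.3)
    lo = SourceSignature("lo", -10.0, 0.3)
    f_true = 0.7
    rng = np.random.default_rng(3)
    obs = f_true * hi.mean + (1 - f_true) * lo.mean + rng.normal(0, 0.3, 300)
    post = fit_mixing_model(obs, [hi, lo], NO_OFFSET, McmcSettings(seed=4, **FAST))
    oracle = closed_form_two_source(float(obs.mean()), hi, lo)
    assert summarize(post).loc["hi", "mean"] == pytest.approx(oracle, abs=0.03)


def test_every_retained_draw_lies_on_the_simplex(sources4, offset_pooled):
    obs = np.array([-2.0, 0.5, 3.0, -4.0])
    post = fit_mixing_model(obs, sources4, offset_pooled,
                            McmcSettings(seed=5, **FAST))
    draws = post.draws
    assert np.all(draws >= 0) and np.all(draws <= 1)
    assert np.allclose(draws.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(post.residual_sd_draws > 0)


def test_identical_seed_reproduces_draws(sources3, offset_pooled):
    obs = np.array([1.0, -3.0, 0.2, 5.0])
    settings = McmcSettings(seed=9, **FAST)
    a = fit_mixing_model(obs, sources3, offset_pooled, settings)
    b = fit_mixing_model(obs, sources3, offset_pooled, settings)
    np.testing.assert_array_equal(a.draws, b.draws)
    np.testing.assert_array_equal(a.residual_sd_draws, b.residual_sd_draws)


def test_source_permutation_permutes_columns(sources4, offset_pooled):
    obs = np.array([0.0, 1.5, -2.0])
    settings = McmcSettings(seed=6, **FAST)
    a = fit_mixing_model(obs, sources4, offset_pooled, settings)
    perm = [2, 0, 3, 1]
    b = fit_mixing_model(obs, [sources4[i] for i in perm], offset_pooled, settings)
    assert b.source_names == [sources4[i].name for i in perm]
    np.testing.assert_array_equal(a.draws[:, perm], b.draws)


def test_summary_matches_column_means():
    rng = np.random.default_rng(12)
    raw = rng.dirichlet(np.ones(3), size=(2, 100))
    post = PosteriorContributions(raw, np.ones((2, 100)), ["a", "b", "c"])
    summary = summarize(post)
    flat = raw.reshape(-1, 3)
    np.testing.assert_allclose(summary["mean"], flat.mean(axis=0))
    np.testing.assert_allclose(summary["sd"], flat.std(axis=0, ddof=1))
    np.testing.assert_allclose(summary["ci2.5"], np.quantile(flat, 0.025, axis=0))


def test_summary_of_constant_draws_is_degenerate():
    raw = np.full((2, 50, 3), 1.0 / 3.0)
    post = PosteriorContributions(raw, np.ones((2, 50)), ["a", "b", "c"])
    summary = summarize(post)
    assert np.allclose(summary["sd"], 0.0)
    assert np.allclose(summary["ci2.5"], summary["ci97.5"])


def _classic_split_rhat(chains: np.ndarray) -> float:
    """Direct between/within split potential-scale-reduction."""
    c, n = chains.shape
    halves = chains.reshape(2 * c, n // 2)
    m, h = halves.shape
    w = halves.var(axis=1, ddof=1).mean()
    b = h * halves.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((h - 1) / h * w + b / h) / w))


class TestConvergence:
    def _posterior(self, chains: np.ndarray) -> PosteriorContributions:
        c, n = chains.shape
        fracs = np.stack([chains, 1.0 - chains], axis=-1)
        return PosteriorContributions(fracs, np.ones((c, n)), ["a", "b"])

    def test_stationary_chains_pass(self):
        rng = np.random.default_rng(0)
        chains = rng.beta(5, 5, size=(4, 500))
        flags = check_convergence(self._posterior(chains))
        assert flags["a"] and flags["b"]

    def test_shifted_chain_fails(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(0.3, 0.01, size=(4, 500))
        chains[0] += 0.3
        flags = check_convergence(self._posterior(np.clip(chains, 0, 1)))
        assert not flags["a"]

    def test_statistic_matches_direct_computation(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(0.5, 0.1, size=(4, 400))
        chains[1] += 0.05
        post = self._posterior(np.clip(chains, 0, 1))
        from noxtrace.mixing import _rhat

        stats = _rhat(post.chain_fractions, post.chain_residual_sd,
                      post.source_names)
        expected = _classic_split_rhat(post.chain_fractions[:, :, 0])
        assert stats["a"] == pytest.approx(expected, rel=1e-6)

    def test_single_chain_raises(self):
        chains = np.full((1, 100), 0.5)
        with pytest.raises(ConvergenceUnavailableError):
            check_convergence(self._posterior(chains))


def test_degenerate_sources_warn_but_fit(offset_pooled):
    sources = [SourceSignature("a", 5.0, 0.0), SourceSignature("b", 5.0, 0.0),
               SourceSignature("c", 5.0, 0.0)]
    with pytest.warns(NonIdentifiabilityWarning):
        post = fit_mixing_model(np.array([5.0, 5.1]), sources, NO_OFFSET,
                                McmcSettings(seed=0, **FAST))
    assert post.draws.shape[1] == 3


def test_invalid_inputs_rejected(sources3, offset_pooled):
    with pytest.raises(ValueError):
        fit_mixing_model([], sources3, offset_pooled, McmcSettings(**FAST))
    with pytest.raises(ValueError):
        fit_mixing_model([1.0], sources3[:1], offset_pooled, McmcSettings(**FAST))
    with pytest.raises(ValueError):
        McmcSettings(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        McmcSettings(n_chains=1)
    with pytest.raises(ValueError):
        McmcSettings(thin=0)
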