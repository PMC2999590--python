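import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import halfcauchy, norm

from gebma.cohort import CohortSpec, TrueModel, simulate_cohort
from gebma.priors import PriorConfig
from gebma.sampler import (
    ChainConfig,
    ChainState,
    Trace,
    log_likelihood,
    run_chain,
    sample_posterior,
    update_inclusion_probs,
)
from gebma.terms import build_design

from conftest import tiny_two_term_problem


def short_chain(**kw):
    base = dict(n_iter=2_000, n_adapt=400, n_burn=200, seed=1)
    base.update(kw)
    return ChainConfig(**base)


class TestChainConfig:
    def test_retained_length(self):
        assert ChainConfig().n_retained == 16_000
        assert short_chain().n_retained == 1_400

    def test_invalid_protocol(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, n_adapt=80, n_burn=30)


class TestLogLikelihood:
    def test_null_state_is_n_log_half(self, term_set, null_cohort, prior_config):
        design = build_design(null_cohort, term_set)
        y = null_cohort.outcome.to_numpy(float)
        state = ChainState.initial(term_set, prior_config, short_chain(), design.fixed().shape[1])
        assert log_likelihood(state, design, y) == pytest.approx(len(y) * math.log(0.5))

    def test_matches_naive_loop(self, term_set, null_cohort, prior_config):
        """Vectorised log-likelihood equals a per-subject summed recomputation
        with an independent expit implementation."""
        design = build_design(null_cohort, term_set)
        y = null_cohort.outcome.to_numpy(float)
        rng = np.random.default_rng(3)
        state = ChainState.initial(term_set, prior_config, short_chain(), design.fixed().shape[1])
        state.beta_c = rng.normal(0, 0.3, len(state.beta_c))
        state.beta_v = rng.normal(0, 0.3, len(state.beta_v))
        state.I[:] = rng.random(term_set.n_main) < 0.5
        state.J[:] = rng.random(term_set.n_interaction) < 0.5

        from gebma.sampler import _parent_index

        eff = state.effective(_parent_index(term_set))
        Xc, Xv = design.fixed(), design.selectable()
        total = 0.0
        for i in range(len(y)):
            eta_i = float(Xc[i] @ state.beta_c + Xv[i] @ (eff * state.beta_v))
            p_i = 1.0 / (1.0 + math.exp(-eta_i))
            total += math.log(p_i) if y[i] == 1 else math.log(1.0 - p_i)
        assert log_likelihood(state, design, y) == pytest.approx(total, abs=1e-8)

    def test_toggling_zero_coefficient_is_noop(self, term_set, null_cohort, prior_config):
        design = build_design(null_cohort, term_set)
        y = null_cohort.outcome.to_numpy(float)
        state = ChainState.initial(term_set, prior_config, short_chain(), design.fixed().shape[1])
        before = log_likelihood(state, design, y)
        state.I[0] = True  # beta is 0, so the product term contributes nothing
        assert log_likelihood(state, design, y) == pytest.approx(before)

    def test_prior_only_is_zero(self, term_set, prior_config):
        state = ChainState.initial(term_set, prior_config, short_chain(), 0)
        assert log_likelihood(state, None, None, prior_only=True) == 0.0


class TestConjugateProbabilityUpdate:
    def test_posterior_beta_moments(self, term_set, prior_config):
        """p | indicator ~ Beta(a + ind, b + 1 - ind): long-run means match
        the closed form for both indicator values."""
        rng = np.random.default_rng(4)
        state = ChainState.initial(term_set, prior_config, short_chain(), 0)
        state.I[:] = False
        state.I[0] = True  # Beta(2, 3), mean 0.4
        state.J[:] = False  # Beta(2, 3), mean 0.4 for interactions
        draws = np.array([update_inclusion_probs(state, term_set, prior_config, rng).copy()
                          for _ in range(5_000)])
        assert abs(draws[:, 0].mean() - 2 / 5) < 0.01          # included main
        assert abs(draws[:, 1].mean() - 1 / 5) < 0.01          # excluded main: Beta(1,4)
        assert abs(draws[:, term_set.n_main].mean() - 2 / 5) < 0.01  # excluded interaction


@pytest.fixture(scope="module")
def prior_trace(term_set, prior_config):
    cfg = ChainConfig(n_iter=8_000, n_adapt=1_000, n_burn=1_000, seed=9, prior_only=True)
    return run_chain(None, term_set, prior_config, cfg)


class TestPriorRecovery:
    """With the likelihood disabled the chain must reproduce every marginal
    of the joint prior — the sampler's primary correctness oracle."""

    def test_main_inclusion(self, prior_trace, term_set):
        incl = prior_trace.inclusion_probabilities()
        assert abs(incl[list(term_set.main_terms)].mean() - 0.25) < 0.03

    def test_effective_interaction_inclusion(self, prior_trace, term_set):
        incl = prior_trace.inclusion_probabilities()
        assert abs(incl[list(term_set.interaction_names)].mean() - 0.03125) < 0.012

    def test_psi_int_prior(self, prior_trace):
        assert abs(prior_trace.log_psi_int.mean() - 2.3) < 0.1
        assert abs(prior_trace.log_psi_int.var() - 1.0) < 0.25

    def test_sigma_half_cauchy_median(self, prior_trace):
        assert 40 < np.median(prior_trace.sigma) < 250

    def test_inclusion_probability_marginal(self, prior_trace, term_set):
        # p_main marginal stays Beta(1,3): mean 0.25
        assert abs(prior_trace.p[:, : term_set.n_main].mean() - 0.25) < 0.01
        assert abs(prior_trace.p[:, term_set.n_main:].mean() - 0.5) < 0.01

    def test_coefficients_standardised_by_scale(self, prior_trace, term_set):
        """beta_v / (psi_t sigma) is standard normal under the prior."""
        psi = np.ones_like(prior_trace.beta_v)
        psi[:, term_set.n_main:] = np.exp(prior_trace.log_psi_int)[:, None]
        z = prior_trace.beta_v / (psi * prior_trace.sigma[:, None])
        assert abs(z.mean()) < 0.02
        assert abs(z.var() - 1.0) < 0.05

    def test_psi_chain_mixes_without_included_interactions(self, prior_trace):
        x = prior_trace.log_psi_int
        x = x - x.mean()
        lag = 50
        acf = float(x[lag:] @ x[:-lag] / (x @ x))
        assert acf < 0.5


class TestRunChain:
    def test_trace_length_and_determinism(self, term_set, null_cohort, prior_config):
        cfg = short_chain()
        a = run_chain(null_cohort, term_set, prior_config, cfg)
        b = run_chain(null_cohort, term_set, prior_config, cfg)
        assert len(a) == cfg.n_retained
        np.testing.assert_array_equal(a.beta_v, b.beta_v)
        np.testing.assert_array_equal(a.eff, b.eff)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        c = run_chain(null_cohort, term_set, prior_config, cfg.replace(seed=2))
        assert not np.array_equal(a.sigma, c.sigma)

    def test_heredity_holds_at_every_retained_state(self, term_set, null_cohort, prior_config):
        trace = run_chain(null_cohort, term_set, prior_config, short_chain(seed=3))
        nm = term_set.n_main
        for k, (a, b) in enumerate(trace.terms.interaction_terms):
            ia = term_set.main_terms.index(a)
            ib = term_set.main_terms.index(b)
            eff_int = trace.eff[:, nm + k]
            assert np.all(eff_int <= np.minimum(trace.I[:, ia], trace.I[:, ib]))

    def test_seed_replication_tolerance(self, term_set, null_cohort, prior_config):
        cfg = short_chain(n_iter=3_000, n_adapt=500, n_burn=250)
        a = run_chain(null_cohort, term_set, prior_config, cfg.replace(seed=5))
        b = run_chain(null_cohort, term_set, prior_config, cfg.replace(seed=6))
        diff = (a.inclusion_probabilities() - b.inclusion_probabilities()).abs()
        assert diff.max() < 0.03

    def test_acceptance_rates_in_contract_band(self, term_set, null_cohort, prior_config):
        trace = run_chain(null_cohort, term_set, prior_config,
                          short_chain(n_iter=3_000, n_adapt=800, n_burn=200, seed=7))
        # only blocks proposed often enough for the rate to be meaningful
        rates = {k: v for k, v in trace.acceptance.items()
                 if k.startswith("beta_c") or k in ("sigma", "psi_int")}
        for name, rate in rates.items():
            assert 0.1 <= rate <= 0.6, (name, rate)

    def test_data_required_without_prior_only(self, term_set, prior_config):
        with pytest.raises(ValueError):
            run_chain(None, term_set, prior_config, short_chain())

    def test_strong_effect_is_selected(self, term_set, prior_config):
        spec = CohortSpec(n_cases=250, n_controls=400, superpopulation_factor=10, seed=8)
        data = simulate_cohort(spec, TrueModel(coefficients={"nat2": np.log(4.0)}), seed=8)
        trace = run_chain(data, term_set, prior_config,
                          short_chain(n_iter=2_500, n_adapt=500, n_burn=250, seed=8))
        assert trace.inclusion_probabilities()["nat2"] > 0.9


class TestTinySpaceOracles:
    def test_sigma_sampled_inclusion_matches_quadrature(self):
        """1-term universe: posterior inclusion with sigma *sampled* matches
        numerical integration over (beta, sigma) — validates the collapsed
        variance kernel against an independent oracle."""
        from gebma.terms import DesignMatrix, TermSet

        ts = TermSet(fixed_terms=(), main_terms=("a",), interaction_terms=(),
                     pathway_map={}, exposure=None)
        rng = np.random.default_rng(5)
        n = 40
        xa = rng.normal(size=n)
        xa -= xa.mean()
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-xa))).astype(float)
        design = DesignMatrix(frame=pd.DataFrame({"a": xa}), fixed_names=(),
                              main_names=("a",), interaction_names=(), centers={},
                              terms=ts, has_intercept=False)
        pri = PriorConfig()
        bgrid = np.linspace(-15, 15, 2001)
        ll = bgrid[:, None] * xa[None, :]
        log_ratio = ll @ y - np.logaddexp(0, ll).sum(axis=1) - n * np.log(0.5)
        Lr = np.exp(log_ratio)
        sgrid = np.exp(np.linspace(np.log(1e-3), np.log(5e3), 400))
        inner = np.array([np.trapezoid(Lr * norm.pdf(bgrid, 0, s), bgrid) for s in sgrid])
        w = halfcauchy.pdf(sgrid, scale=pri.cauchy_scale)
        bf = np.trapezoid(inner * w * sgrid, np.log(sgrid))
        odds = (0.25 / 0.75) * bf
        expected = odds / (1 + odds)

        cfg = ChainConfig(n_iter=24_000, n_adapt=2_000, n_burn=2_000, seed=1,
                          sample_psi_int=False)
        trace = sample_posterior(design, y, ts, pri, cfg)
        assert abs(trace.eff.mean() - expected) < 0.03

    def test_conditional_mean_matches_penalised_mle(self):
        """Posterior mean coefficient given inclusion is close to the
        penalised-logistic point estimate (quadratic-approximation check)."""
        from gebma.sampler import _ridge_logistic

        ts, design, y = tiny_two_term_problem()
        pri = PriorConfig()
        cfg = ChainConfig(n_iter=12_000, n_adapt=1_000, n_burn=1_000, seed=2,
                          sample_sigma=False, sample_psi_int=False, sigma_init=1.5)
        trace = sample_posterior(design, y, ts, pri, cfg)
        Xa = design.frame[["a"]].to_numpy()
        coef, se = _ridge_logistic(Xa, y)
        included = trace.eff[:, 0].astype(bool)
        cond = trace.beta_v[included, 0]
        # allow the prior's shrinkage: within 2 posterior SDs
        assert abs(cond.mean() - coef[0]) < 2 * cond.std()


class TestTracePersistence:
    def test_save_load_roundtrip(self, term_set, null_cohort, prior_config, tmp_path):
        trace = run_chain(null_cohort, term_set, prior_config,
                          short_chain(n_iter=800, n_adapt=200, n_burn=100))
        trace.save(tmp_path / "run")
        back = Trace.load(tmp_path / "run")
        np.testing.assert_allclose(back.beta_v, trace.beta_v)
        np.testing.assert_array_equal(back.eff, trace.eff)
        assert back.terms.selectable_terms == trace.terms.selectable_terms
        pd.testing.assert_series_equal(
            back.inclusion_probabilities(), trace.inclusion_probabilities()
        )
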