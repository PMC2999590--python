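import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gebma.sampler import ChainConfig, Trace
from gebma.summarize import (
    bf_all,
    bf_vs_null,
    default_sensitivity_grid,
    kass_raftery_category,
    model_summaries,
    sensitivity_grid,
    term_summaries,
    term_table,
    variable_bayes_factor,
)
from gebma.terms import build_term_set


def make_trace(terms, eff, beta, p=None, sigma=None):
    """Assemble a synthetic Trace for a mains-only universe."""
    R, m = eff.shape
    nm = terms.n_main
    return Trace(
        terms=terms,
        fixed_names=(),
        beta_c=np.zeros((R, 0)),
        beta_v=beta,
        I=eff[:, :nm].astype(np.uint8),
        J=eff[:, nm:].astype(np.uint8),
        eff=eff.astype(np.uint8),
        p=p if p is not None else np.full((R, m), 0.25),
        sigma=sigma if sigma is not None else np.ones(R),
        log_psi_int=np.full(R, 2.3),
        loglik=np.zeros(R),
    )


@pytest.fixture(scope="module")
def two_main_terms():
    return build_term_set(genes=("g1", "g2"), pathways={"g1": "P", "g2": "P"}, exposure=None)


class TestVariableBayesFactor:
    @pytest.mark.parametrize(
        "post,prior,expected",
        [
            (0.26, 0.25, 1.05),   # mild evidence for the top-ranked gene
            (0.13, 0.25, 0.45),
            (0.06, 0.25, 0.19),
            (0.12, 0.25, 0.41),
            (0.09, 0.25, 0.30),
        ],
    )
    def test_reported_values(self, post, prior, expected):
        assert round(variable_bayes_factor(post, prior), 2) == pytest.approx(expected)

    @given(st.floats(0.001, 0.999))
    def test_identity_when_post_equals_prior(self, p):
        assert variable_bayes_factor(p, p) == pytest.approx(1.0)

    def test_degenerate_probabilities_flagged_not_raised(self):
        assert variable_bayes_factor(1.0, 0.25) == np.inf
        assert variable_bayes_factor(0.0, 0.25) == 0.0

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            variable_bayes_factor(1.2, 0.25)


class TestModelBayesFactors:
    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    def test_probability_ratio_arithmetic(self, post, prior):
        """BF_all recomputed as a one-line probability ratio to 10 digits."""
        assert bf_all(post, prior) == pytest.approx(post / prior, rel=1e-10)

    def test_odds_convention(self):
        assert bf_all(0.5, 0.25, convention="odds") == pytest.approx(3.0)
        with pytest.raises(ValueError):
            bf_all(0.5, 0.25, convention="bogus")

    def test_null_vs_itself_is_one(self):
        assert bf_vs_null(0.59, 0.59) == pytest.approx(1.0)


class TestKassRaftery:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (0.5, "none"),
            (1.0, "none"),
            (1.05, "very mild"),
            (3.0, "very mild"),
            (3.8, "positive"),
            (20.0, "positive"),
            (21.0, "strong"),
            (150.0, "strong"),
            (151.0, "very strong"),
        ],
    )
    def test_bins(self, bf, label):
        assert kass_raftery_category(bf) == label

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            kass_raftery_category(-0.1)


class TestTermSummaries:
    def test_never_included(self, two_main_terms, prior_config):
        R = 400
        eff = np.zeros((R, 3), dtype=int)
        beta = np.zeros((R, 3))
        s = term_summaries(make_trace(two_main_terms, eff, beta), two_main_terms, prior_config)
        assert s[0].or_marginal == pytest.approx(1.0)
        assert s[0].or_conditional is None
        assert s[0].posterior_inclusion == 0.0
        assert s[0].bayes_factor == 0.0

    def test_always_included_constant_coefficient(self, two_main_terms, prior_config):
        R = 400
        eff = np.zeros((R, 3), dtype=int)
        eff[:, 0] = 1
        beta = np.zeros((R, 3))
        beta[:, 0] = np.log(1.19)
        s = term_summaries(make_trace(two_main_terms, eff, beta), two_main_terms, prior_config)
        assert s[0].or_marginal == pytest.approx(1.19)
        assert s[0].or_conditional == pytest.approx(1.19)
        assert s[0].posterior_inclusion == 1.0

    def test_shrinkage_of_marginal_towards_one(self, two_main_terms, prior_config):
        """Intermittent inclusion shrinks the marginal OR towards 1 while the
        conditional OR stays at the within-model effect size."""
        rng = np.random.default_rng(0)
        R = 200_000
        eff = np.zeros((R, 3), dtype=int)
        eff[:, 0] = rng.random(R) < 0.26
        beta = np.zeros((R, 3))
        beta[:, 0] = np.log(1.19)
        s = term_summaries(make_trace(two_main_terms, eff, beta), two_main_terms, prior_config)[0]
        assert s.or_conditional == pytest.approx(1.19)
        assert s.or_marginal == pytest.approx(np.exp(0.26 * np.log(1.19)), abs=2e-3)
        assert s.or_marginal == pytest.approx(1.046, abs=2e-3)

    def test_empty_trace_errors(self, two_main_terms, prior_config):
        empty = make_trace(two_main_terms, np.zeros((0, 3), dtype=int), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            term_summaries(empty, two_main_terms, prior_config)

    def test_table_shape(self, two_main_terms, prior_config):
        eff = np.zeros((50, 3), dtype=int)
        s = term_summaries(make_trace(two_main_terms, eff, np.zeros((50, 3))),
                           two_main_terms, prior_config)
        table = term_table(s)
        assert list(table.term) == list(two_main_terms.selectable_terms)
        assert {"or_marginal", "or_conditional", "pr_post", "bf", "evidence"} <= set(table.columns)


class TestModelSummaries:
    def test_visit_frequencies_and_bayes_factors(self, two_main_terms, prior_config):
        R = 1000
        eff = np.zeros((R, 3), dtype=int)
        eff[:600, 0] = 1          # model {g1} visited 60%
        beta = np.zeros((R, 3))
        table = model_summaries(make_trace(two_main_terms, eff, beta),
                                two_main_terms, prior_config)
        assert table.posterior.sum() == pytest.approx(1.0, abs=1e-9)
        row_g1 = table[table.model == "g1"].iloc[0]
        assert row_g1.posterior == pytest.approx(0.6)
        assert row_g1.prior == pytest.approx(0.25 * 0.75)
        assert row_g1.bf_all == pytest.approx(0.6 / (0.25 * 0.75))
        row_null = table[table.model == "NULL"].iloc[0]
        assert row_null.bf_0 == pytest.approx(1.0)
        assert row_g1.bf_0 == pytest.approx(0.6 / 0.4)

    def test_null_never_visited_flagged(self, two_main_terms, prior_config):
        eff = np.ones((100, 3), dtype=int)
        with pytest.warns(UserWarning, match="NULL"):
            table = model_summaries(make_trace(two_main_terms, eff, np.zeros((100, 3))),
                                    two_main_terms, prior_config)
        assert np.isnan(table.bf_0).all()


class TestSensitivityGrid:
    def test_default_grid_layout(self):
        grid = default_sensitivity_grid()
        names = [g["name"] for g in grid]
        assert names[0] == "baseline"
        assert len(names) == 8
        assert {"a_main", "b_main"} <= set(grid[1])

    def test_grid_runs_and_records_errors(self, null_cohort, prior_config):
        ts = build_term_set()
        grid = [
            {"name": "baseline"},
            {"name": "broken", "a_main": -1.0},   # invalid prior: recorded, not raised
        ]
        chain = ChainConfig(n_iter=400, n_adapt=100, n_burn=50, seed=3)
        table = sensitivity_grid(null_cohort, ts, grid, chain, prior_config)
        ok = table[table.scenario == "baseline"]
        assert len(ok) == 20 and ok.error.isna().all()
        bad = table[table.scenario == "broken"]
        assert len(bad) == 1 and bad.error.notna().all()
        # distinct sub-seeds per scenario
        assert ok.seed.iloc[0] != bad.seed.iloc[0]
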