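"""scikit-learn-style estimators wrapping the model-averaging sampler and
the stepwise baseline.

Both estimators take a cohort DataFrame ``X`` with the raw columns (age,
famhist, menopause, packyears and the genotype codings) and a 0/1 outcome
``y``; design construction (encoding, centering, interaction products)
happens inside ``fit`` and is replayed on new data at prediction time using
the stored training centers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .baseline import backward_stepwise_aic
from .priors import PriorConfig
from .sampler import ChainConfig, sample_posterior
from .summarize import model_summaries, term_summaries, term_table
from .terms import TermSet, build_design, default_term_set

__all__ = ["BMALogisticRegression", "StepwiseLogisticAIC"]


class BMALogisticRegression(BaseEstimator, ClassifierMixin):
    """Bayes-model-averaged logistic regression with spike-and-slab selection.

    Parameters mirror :class:`~gebma.priors.PriorConfig` and
    :class:`~gebma.sampler.ChainConfig`; pass instances to override defaults.

    Fitted attributes
    -----------------
    trace_ : Trace
        Retained MCMC draws.
    inclusion_probabilities_ : pandas.Series
        Posterior inclusion probability per selectable term.
    term_summary_ : pandas.DataFrame
        Odds ratios, inclusion probabilities and Bayes factors per term.
    model_summary_ : pandas.DataFrame
        Visited models with posterior/prior probabilities and Bayes factors.
    """

    def __init__(
        self,
        priors: PriorConfig | None = None,
        terms: TermSet | None = None,
        n_iter: int = 20_000,
        n_adapt: int = 2_000,
        n_burn: int = 2_000,
        thin: int = 1,
        random_state: int = 0,
        menopause_coding: str = "dummy",
    ):
        self.priors = priors
        self.terms = terms
        self.n_iter = n_iter
        self.n_adapt = n_adapt
        self.n_burn = n_burn
        self.thin = thin
        self.random_state = random_state
        self.menopause_coding = menopause_coding

    def _chain_config(self) -> ChainConfig:
        return ChainConfig(
            n_iter=self.n_iter,
            n_adapt=self.n_adapt,
            n_burn=self.n_burn,
            thin=self.thin,
            seed=self.random_state,
        )

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a cohort DataFrame")
        y = np.asarray(y, float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        terms = self.terms if self.terms is not None else default_term_set()
        priors = self.priors if self.priors is not None else PriorConfig()
        design = build_design(X, terms, menopause_coding=self.menopause_coding)
        self.terms_ = terms
        self.priors_ = priors
        self.design_ = design
        self.trace_ = sample_posterior(design, y, terms, priors, self._chain_config())
        self.inclusion_probabilities_ = self.trace_.inclusion_probabilities()
        self._summaries_ = term_summaries(self.trace_, terms, priors)
        self.term_summary_ = term_table(self._summaries_)
        self.model_summary_ = model_summaries(self.trace_, terms, priors)
        # plug-in posterior means of the averaged coefficients
        self.coef_fixed_ = self.trace_.beta_c.mean(axis=0)
        self.coef_ = (self.trace_.eff * self.trace_.beta_v).mean(axis=0)
        self.classes_ = np.array([0, 1])
        return self

    def _eta(self, X: pd.DataFrame) -> np.ndarray:
        design = build_design(
            X, self.terms_, centers=self.design_.centers, menopause_coding=self.menopause_coding
        )
        return design.fixed() @ self.coef_fixed_ + design.selectable() @ self.coef_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Plug-in disease probability from the posterior-mean averaged model."""
        p = expit(self._eta(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class StepwiseLogisticAIC(BaseEstimator, ClassifierMixin):
    """Backward stepwise logistic regression by AIC under strong heredity.

    ``start`` chooses the initial model: ``"main"`` (exposure + genes) or
    ``"all"`` (mains plus every legal pairwise interaction).
    """

    def __init__(
        self,
        start: str = "all",
        terms: TermSet | None = None,
        menopause_coding: str = "dummy",
    ):
        self.start = start
        self.terms = terms
        self.menopause_coding = menopause_coding

    def fit(self, X: pd.DataFrame, y):
        if self.start not in ("main", "all"):
            raise ValueError("start must be 'main' or 'all'")
        terms = self.terms if self.terms is not None else default_term_set()
        design = build_design(X, terms, menopause_coding=self.menopause_coding)
        y = np.asarray(y, float)
        start_terms = terms.main_terms if self.start == "main" else terms.selectable_terms
        result = backward_stepwise_aic(design, terms, y, start_terms)
        self.terms_ = terms
        self.design_ = design
        self.selected_terms_ = result.selected
        self.path_ = result.path
        self.fit_ = result.final_fit
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design = build_design(
            X, self.terms_, centers=self.design_.centers, menopause_coding=self.menopause_coding
        )
        eta = design.frame[list(self.fit_.columns)].to_numpy(float) @ self.fit_.params.to_numpy()
        p = expit(eta)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
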