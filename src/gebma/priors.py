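"""Hierarchical prior for spike-and-slab logistic model averaging.

Each selectable term carries its own inclusion probability ``p`` with a beta
prior — Beta(1, 3) for main effects (marginal inclusion 0.25) and Beta(2, 2)
for interactions. The interaction indicator is decomposed as
``I_eff = I_r * I_s * J`` with ``J ~ Bernoulli(p_int)``: an interaction can
only be effectively included under strong heredity, its conditional inclusion
probability given both parents is 0.5, and its marginal prior inclusion is
0.25 * 0.25 * 0.5 = 0.03125.

Included coefficients are Normal(0, (psi_t * sigma)^2) where ``sigma`` is a
shared scale with a half-Cauchy(100) prior and ``psi_t`` a variance-inflation
factor per interaction level: psi_main = 1 fixed, log(psi_int) ~ N(2.3, 1)
(the slightly informative prior that keeps the update proper when no
interaction is currently in the model). Fixed adjustment covariates get a
diffuse Normal(0, 10^2) prior.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy import stats

from .terms import TermSet, heredity_closure

__all__ = [
    "PriorConfig",
    "beta_params_for_mean",
    "marginal_inclusion_prior",
    "conditional_interaction_prior",
    "model_prior_probability",
    "enumerate_legal_models",
    "log_prior_density",
    "log_sigma_prior",
]


@dataclass
class PriorConfig:
    """All hyperparameters of the hierarchical prior."""

    a_main: float = 1.0
    b_main: float = 3.0
    a_int: float = 2.0
    b_int: float = 2.0
    mu_int: float = 2.3      # mean of log(psi_int)
    tau_int: float = 1.0     # variance of log(psi_int)
    psi_main: float = 1.0
    cauchy_scale: float = 100.0   # half-Cauchy scale for sigma
    fixed_coef_sd: float = 10.0   # diffuse prior SD for adjustment coefficients
    half_cauchy_on: str = "sigma"  # "sigma" (default) or "sigma2"

    def __post_init__(self):
        for name in ("a_main", "b_main", "a_int", "b_int", "tau_int",
                     "psi_main", "cauchy_scale", "fixed_coef_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.half_cauchy_on not in ("sigma", "sigma2"):
            raise ValueError("half_cauchy_on must be 'sigma' or 'sigma2'")

    @property
    def mean_p_main(self) -> float:
        return self.a_main / (self.a_main + self.b_main)

    @property
    def mean_p_int(self) -> float:
        return self.a_int / (self.a_int + self.b_int)

    def replace(self, **kw) -> "PriorConfig":
        cfg = asdict(self)
        cfg.update(kw)
        return PriorConfig(**cfg)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def beta_params_for_mean(mean: float, concentration: float) -> tuple[float, float]:
    """Beta shapes (a, b) with the requested mean and a + b = concentration."""
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly inside (0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return (mean * concentration, (1.0 - mean) * concentration)


def conditional_interaction_prior(cfg: PriorConfig) -> float:
    """P(interaction included | both parents included) = E[p_int]."""
    return cfg.mean_p_int


def marginal_inclusion_prior(term: str, terms: TermSet, cfg: PriorConfig) -> float:
    """Marginal prior probability that a term is effectively included."""
    terms.validate_term(term)
    if not terms.is_interaction(term):
        return cfg.mean_p_main
    a, b = terms.parents(term)
    return (
        marginal_inclusion_prior(a, terms, cfg)
        * marginal_inclusion_prior(b, terms, cfg)
        * cfg.mean_p_int
    )


def model_prior_probability(model, terms: TermSet, cfg: PriorConfig) -> float:
    """Closed-form prior probability of a model (set of included terms).

    Independent beta-Bernoulli per term: each main contributes E[p_main] or
    1 - E[p_main]; each interaction whose parents are both present
    contributes E[p_int] or 1 - E[p_int]; interactions with a missing parent
    are forced out (factor 1). Sums to 1 over the heredity-legal model space.
    """
    model = set(model)
    legal, violators = heredity_closure(model, terms)
    if not legal:
        raise ValueError(f"model violates strong heredity: {violators}")
    prob = 1.0
    pm, pi = cfg.mean_p_main, cfg.mean_p_int
    for t in terms.main_terms:
        prob *= pm if t in model else 1.0 - pm
    for name, (a, b) in terms.heredity().items():
        if a in model and b in model:
            prob *= pi if name in model else 1.0 - pi
    return prob


def enumerate_legal_models(terms: TermSet):
    """Yield every heredity-legal model as a sorted tuple of term names."""
    import itertools

    mains = terms.main_terms
    hered = terms.heredity()
    for r in range(len(mains) + 1):
        for sub in itertools.combinations(mains, r):
            present = set(sub)
            avail = [n for n, (a, b) in hered.items() if a in present and b in present]
            for k in range(len(avail) + 1):
                for ints in itertools.combinations(avail, k):
                    yield tuple(sorted(sub + ints))


def log_prior_density(state, terms: TermSet, cfg: PriorConfig) -> float:
    """Joint log prior density of a chain state.

    Sums beta densities for each per-term inclusion probability, Bernoulli
    masses for the main indicators ``I`` and free interaction indicators
    ``J``, normal densities for every selectable coefficient (coefficients
    retain their prior when excluded), the log-normal prior of psi_int, the
    half-Cauchy prior of sigma, and diffuse normals for the adjustment
    coefficients.
    """
    if state.sigma <= 0 or state.psi_int <= 0:
        raise ValueError("sigma and psi_int must be positive")
    n_main = terms.n_main
    p = np.asarray(state.p, float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("inclusion probabilities must lie in (0,1)")
    p_main, p_int = p[:n_main], p[n_main:]
    I = np.asarray(state.I, float)
    J = np.asarray(state.J, float)

    lp = stats.beta.logpdf(p_main, cfg.a_main, cfg.b_main).sum()
    lp += stats.beta.logpdf(p_int, cfg.a_int, cfg.b_int).sum()
    lp += np.sum(I * np.log(p_main) + (1 - I) * np.log1p(-p_main))
    lp += np.sum(J * np.log(p_int) + (1 - J) * np.log1p(-p_int))

    beta_v = np.asarray(state.beta_v, float)
    sd = np.concatenate([
        np.full(n_main, cfg.psi_main * state.sigma),
        np.full(terms.n_interaction, state.psi_int * state.sigma),
    ])
    lp += stats.norm.logpdf(beta_v, 0.0, sd).sum()
    lp += stats.norm.logpdf(np.log(state.psi_int), cfg.mu_int, np.sqrt(cfg.tau_int))
    lp += log_sigma_prior(state.sigma, cfg)
    lp += stats.norm.logpdf(np.asarray(state.beta_c, float), 0.0, cfg.fixed_coef_sd).sum()
    return float(lp)


def log_sigma_prior(sigma: float, cfg: PriorConfig) -> float:
    """Log prior density of sigma (expressed as a density in sigma itself).

    The default places the half-Cauchy on the scale sigma; the ``sigma2``
    switch places it on sigma^2 instead (with the change-of-variable
    Jacobian 2*sigma).
    """
    if sigma <= 0:
        return -np.inf
    if cfg.half_cauchy_on == "sigma":
        return float(stats.halfcauchy.logpdf(sigma, scale=cfg.cauchy_scale))
    return float(
        stats.halfcauchy.logpdf(sigma**2, scale=cfg.cauchy_scale) + np.log(2.0 * sigma)
    )
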