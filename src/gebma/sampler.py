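"""Metropolis-within-Gibbs sampler for spike-and-slab logistic model averaging.

The model is the Kuo-Mallick product parameterisation of Bayesian variable
selection for a logistic regression:

    logit P(Y=1 | X) = sum_c beta_c X_c + sum_v Ieff_v beta_v X_v

where every selectable coefficient ``beta_v`` retains its prior
N(0, (psi_t sigma)^2) whether or not the term is currently in the model, and
``Ieff`` is the effective inclusion indicator: the main-effect indicator
``I`` for mains and the product ``I_r I_s J`` for interactions (strong
heredity enforced by construction).

One sweep updates, in order:

1. indicators ``I``/``J`` in random-scan order by Metropolised toggles that
   propose a fresh coefficient from its prior (prior and proposal densities
   cancel, leaving likelihood ratio times Bernoulli prior odds);
2. coefficients — random-walk Metropolis for the adjustment block and every
   effectively included selectable term;
3. per-term inclusion probabilities ``p`` by their exact beta conjugate draw;
4. variance components — random-walk Metropolis on log(sigma) (Jacobian
   corrected) and log(psi_int), with the coefficients of currently excluded
   terms integrated out (their priors integrate to 1);
5. a refresh of every excluded coefficient from its prior under the new
   scales (completing the partially collapsed Gibbs step of 4).

Proposal scales adapt by Robbins-Monro towards a 0.35 acceptance rate during
the first ``n_adapt`` iterations only, then freeze so detailed balance holds
for the retained part of the chain. With ``prior_only`` the likelihood is
identically zero: coefficient conditionals reduce to their priors and are
drawn exactly, while the indicator, probability and variance kernels run
unchanged — the basis of the prior-recovery correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .priors import PriorConfig, log_sigma_prior
from .terms import DesignMatrix, TermSet, build_design

__all__ = [
    "ChainConfig",
    "ChainState",
    "Trace",
    "run_chain",
    "sample_posterior",
    "log_likelihood",
    "update_inclusion_probs",
    "update_indicators",
    "update_coefficients",
    "update_variance_components",
]


@dataclass
class ChainConfig:
    """Chain protocol: 20,000 total iterations by default, of which the
    first 2,000 adapt proposal scales and the next 2,000 are burn-in, leaving
    16,000 retained draws."""

    n_iter: int = 20_000
    n_adapt: int = 2_000
    n_burn: int = 2_000
    thin: int = 1
    seed: int = 0
    prior_only: bool = False
    sample_sigma: bool = True
    sample_psi_int: bool = True
    sigma_init: float = 1.0
    psi_int_init: float = float(np.exp(2.3))
    initial_proposal_sd: float = 0.1
    target_accept: float = 0.35
    #: inclusion-toggle proposal for the coefficient: "auto" uses a
    #: likelihood-informed normal approximation when data are present (the
    #: prior proposal otherwise); "prior" always draws from the prior.
    indicator_proposal: str = "auto"

    def __post_init__(self):
        if self.n_adapt + self.n_burn >= self.n_iter:
            raise ValueError("n_adapt + n_burn must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_adapt - self.n_burn) // self.thin

    def replace(self, **kw) -> "ChainConfig":
        cfg = asdict(self)
        cfg.update(kw)
        return ChainConfig(**cfg)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class ChainState:
    """Current values of every sampled quantity."""

    beta_c: np.ndarray      # adjustment coefficients (incl. intercept)
    beta_v: np.ndarray      # selectable coefficients (mains then interactions)
    I: np.ndarray           # main-effect indicators (bool)
    J: np.ndarray           # free interaction indicators (bool)
    p: np.ndarray           # per-term inclusion probabilities
    sigma: float
    psi_int: float

    @classmethod
    def initial(cls, terms: TermSet, priors: PriorConfig, chain: ChainConfig,
                n_fixed: int) -> "ChainState":
        """Null-model start: all indicators off, coefficients zero,
        p at its prior mean."""
        m, ni = terms.n_main, terms.n_interaction
        return cls(
            beta_c=np.zeros(n_fixed),
            beta_v=np.zeros(m + ni),
            I=np.zeros(m, dtype=bool),
            J=np.zeros(ni, dtype=bool),
            p=np.concatenate([
                np.full(m, priors.mean_p_main),
                np.full(ni, priors.mean_p_int),
            ]),
            sigma=chain.sigma_init,
            psi_int=chain.psi_int_init,
        )

    def effective(self, parent_idx: np.ndarray) -> np.ndarray:
        """Effective indicator vector (mains then interactions)."""
        if len(parent_idx):
            eff_int = self.I[parent_idx[:, 0]] & self.I[parent_idx[:, 1]] & self.J
        else:
            eff_int = self.J
        return np.concatenate([self.I, eff_int])


def _parent_index(terms: TermSet) -> np.ndarray:
    lookup = {t: i for i, t in enumerate(terms.main_terms)}
    if terms.n_interaction == 0:
        return np.zeros((0, 2), dtype=int)
    return np.array([[lookup[a], lookup[b]] for a, b in terms.interaction_terms])


def _softplus_sum(eta: np.ndarray) -> float:
    return float(np.logaddexp(0.0, eta).sum())


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x: float, mu: float, sd: float) -> float:
    return -_LOG_SQRT_2PI - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _ridge_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-2,
                    n_iter: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Lightly ridge-penalised logistic IRLS; returns (coef, se).

    Used only to build Metropolis proposal distributions (any inaccuracy is
    corrected by the acceptance ratio), so a small penalty keeping the solve
    well-posed under near-separation is harmless.
    """
    k = X.shape[1]
    beta = np.zeros(k)
    pen = ridge * np.eye(k)
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X.T * w) @ X + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X + pen)
    return beta, np.sqrt(np.diag(cov))


def log_likelihood(state: ChainState, design: DesignMatrix | None, outcome,
                   prior_only: bool = False) -> float:
    """Bernoulli-logit log-likelihood at a state (0 in prior-only mode)."""
    if prior_only:
        return 0.0
    if design is None:
        raise ValueError("design required unless prior_only")
    parent_idx = _parent_index(design.terms)
    eff = state.effective(parent_idx)
    eta = design.fixed() @ state.beta_c + design.selectable() @ (eff * state.beta_v)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    y = np.asarray(outcome, float)
    return float(y @ eta) - _softplus_sum(eta)


class _Sampler:
    """Mutable sampling context with an incrementally maintained linear
    predictor. Not part of the public API."""

    def __init__(self, state: ChainState, design: DesignMatrix | None, outcome,
                 terms: TermSet, priors: PriorConfig, chain: ChainConfig,
                 rng: np.random.Generator):
        self.state = state
        self.terms = terms
        self.priors = priors
        self.chain = chain
        self.rng = rng
        self.prior_only = chain.prior_only
        self.parent_idx = _parent_index(terms)
        self.n_main = terms.n_main
        self.n_int = terms.n_interaction
        self.m = self.n_main + self.n_int
        # children[i] = interaction positions having main i as a parent
        self.children = [[] for _ in range(self.n_main)]
        for k, (r, s) in enumerate(self.parent_idx):
            self.children[r].append(k)
            self.children[s].append(k)
        if self.prior_only:
            self.Xc = None
            self.Xv = None
            self.y = None
            self.n_fixed = len(state.beta_c)
        else:
            assert design is not None
            self.Xc = design.fixed()
            self.Xv = design.selectable()
            self.y = np.asarray(outcome, float)
            self.n_fixed = self.Xc.shape[1]
        self.eff = state.effective(self.parent_idx)
        self.eta = None
        self.ll = 0.0
        if not self.prior_only:
            self.eta = self.Xc @ state.beta_c + self.Xv @ (self.eff * state.beta_v)
            self.ll = self._ll(self.eta)
        # likelihood-informed toggle proposals: per-term normal approximation
        # N(mu_j, s_j^2) from a lightly penalised adjusted GLM fit
        self.prop_mu = np.zeros(self.m)
        self.prop_sd = np.zeros(self.m)
        self.informed = (not self.prior_only) and chain.indicator_proposal == "auto"
        if self.informed:
            for j in range(self.m):
                if j < self.n_main:
                    cols = [j]
                else:
                    r, s = self.parent_idx[j - self.n_main]
                    cols = [int(r), int(s), j]
                X = np.column_stack([self.Xc, self.Xv[:, cols]])
                coef, se = _ridge_logistic(X, self.y)
                self.prop_mu[j] = coef[-1]
                self.prop_sd[j] = max(1.5 * se[-1], 1e-3)
        # adaptation state (log proposal scales)
        ls0 = np.log(chain.initial_proposal_sd)
        self.ls_c = np.full(self.n_fixed, ls0)
        self.ls_v = (np.log(np.maximum(self.prop_sd, 1e-3)) if self.informed
                     else np.full(self.m, ls0))
        self.ls_sigma = 0.0
        self.ls_psi = 0.0
        self.adapt_count_c = np.zeros(self.n_fixed)
        self.adapt_count_v = np.zeros(self.m)
        self.adapt_count_s = 0.0
        self.adapt_count_p = 0.0
        self.adapting = True
        # post-adaptation acceptance bookkeeping {block: [accepts, proposals]}
        self.accept: dict[str, list[float]] = {}

    # -- helpers ---------------------------------------------------------
    def _ll(self, eta) -> float:
        return float(self.y @ eta) - _softplus_sum(eta)

    def _psi(self, j: int) -> float:
        return self.priors.psi_main if j < self.n_main else self.state.psi_int

    def _psi_vec(self) -> np.ndarray:
        return np.concatenate([
            np.full(self.n_main, self.priors.psi_main),
            np.full(self.n_int, self.state.psi_int),
        ])

    def _tally(self, block: str, accepted: float):
        rec = self.accept.setdefault(block, [0.0, 0.0])
        rec[0] += accepted
        rec[1] += 1.0

    def _adapt(self, which: str, idx: int | None, alpha: float):
        if not self.adapting:
            return
        step_of = lambda c: min(0.5, (c + 1.0) ** -0.6)
        t = self.chain.target_accept
        if which == "c":
            self.adapt_count_c[idx] += 1
            self.ls_c[idx] += step_of(self.adapt_count_c[idx]) * (alpha - t)
        elif which == "v":
            self.adapt_count_v[idx] += 1
            self.ls_v[idx] += step_of(self.adapt_count_v[idx]) * (alpha - t)
        elif which == "sigma":
            self.adapt_count_s += 1
            self.ls_sigma += step_of(self.adapt_count_s) * (alpha - t)
        elif which == "psi":
            self.adapt_count_p += 1
            self.ls_psi += step_of(self.adapt_count_p) * (alpha - t)

    # -- kernels ----------------------------------------------------------
    def update_indicators(self):
        """Metropolised toggles in random-scan order.

        Turning a term on proposes a fresh coefficient: from its prior (the
        densities cancel, leaving likelihood ratio times Bernoulli prior
        odds) or, when likelihood-informed proposals are enabled and the
        toggle changes the term's effective status, from the per-term normal
        approximation with the prior/proposal density correction. Turning a
        term off redraws the coefficient from its prior (its value is
        likelihood-inactive afterwards)."""
        st = self.state
        for idx in self.rng.permutation(self.m):
            p = st.p[idx]
            prior_sd = self._psi(idx) * st.sigma
            if idx < self.n_main:
                turn_on = not st.I[idx]
                focal_active = True
            else:
                k = idx - self.n_main
                turn_on = not st.J[k]
                parents_in = bool(st.I[self.parent_idx[k, 0]]) and bool(st.I[self.parent_idx[k, 1]])
                focal_active = parents_in

            use_informed = self.informed and focal_active
            correction = 0.0
            if turn_on:
                if use_informed:
                    new_beta = self.rng.normal(self.prop_mu[idx], self.prop_sd[idx])
                    correction = _norm_logpdf(new_beta, 0.0, prior_sd) - _norm_logpdf(
                        new_beta, self.prop_mu[idx], self.prop_sd[idx])
                else:
                    new_beta = self.rng.normal(0.0, prior_sd)
            else:
                new_beta = self.rng.normal(0.0, prior_sd)
                if use_informed:
                    correction = _norm_logpdf(st.beta_v[idx], self.prop_mu[idx],
                                              self.prop_sd[idx]) - _norm_logpdf(
                        st.beta_v[idx], 0.0, prior_sd)

            if idx < self.n_main:
                i = idx
                delta_cols: list[tuple[int, float]] = []
                old_contrib = st.beta_v[i] if st.I[i] else 0.0
                new_contrib = new_beta if turn_on else 0.0
                delta_cols.append((i, new_contrib - old_contrib))
                flips = []
                for k in self.children[i]:
                    other = self.parent_idx[k, 0] if self.parent_idx[k, 1] == i else self.parent_idx[k, 1]
                    eff_new = turn_on and bool(st.I[other]) and bool(st.J[k])
                    col = self.n_main + k
                    if eff_new != bool(self.eff[col]):
                        flips.append(col)
                        delta_cols.append((col, (1.0 if eff_new else -1.0) * st.beta_v[col]))
            else:
                k = idx - self.n_main
                col = idx
                old_contrib = st.beta_v[col] if self.eff[col] else 0.0
                new_contrib = new_beta if (turn_on and parents_in) else 0.0
                delta_cols = [(col, new_contrib - old_contrib)]
                flips = []

            prior_odds = np.log(p) - np.log1p(-p)
            if not turn_on:
                prior_odds = -prior_odds
            if self.prior_only:
                ll_prop, dll = 0.0, 0.0
            else:
                delta = np.zeros_like(self.eta)
                for col, w in delta_cols:
                    if w != 0.0:
                        delta += w * self.Xv[:, col]
                eta_prop = self.eta + delta
                ll_prop = self._ll(eta_prop)
                dll = ll_prop - self.ll
            logr = dll + prior_odds + correction
            if np.log(self.rng.random()) < logr:
                if idx < self.n_main:
                    st.I[idx] = turn_on
                    self.eff[idx] = turn_on
                    for col in flips:
                        self.eff[col] = not self.eff[col]
                else:
                    st.J[idx - self.n_main] = turn_on
                    self.eff[idx] = turn_on and parents_in
                st.beta_v[idx] = new_beta
                if not self.prior_only:
                    self.eta = eta_prop
                    self.ll = ll_prop

    def update_coefficients(self):
        """Random-walk MH for adjustment and included selectable coefficients.

        With the likelihood disabled every coefficient conditional is its
        prior and is drawn exactly instead (the excluded-coefficient refresh
        handles the selectable block in that case)."""
        st = self.state
        if self.prior_only:
            return
        # adjustment block
        for j in range(self.n_fixed):
            scale = np.exp(self.ls_c[j])
            prop = st.beta_c[j] + scale * self.rng.normal()
            delta = (prop - st.beta_c[j]) * self.Xc[:, j]
            ll_prop = self._ll(self.eta + delta)
            sd = self.priors.fixed_coef_sd
            logr = ll_prop - self.ll - (prop**2 - st.beta_c[j] ** 2) / (2 * sd**2)
            alpha = min(1.0, float(np.exp(min(logr, 0.0))))
            accepted = np.log(self.rng.random()) < logr
            if accepted:
                st.beta_c[j] = prop
                self.eta = self.eta + delta
                self.ll = ll_prop
            self._adapt("c", j, alpha)
            if not self.adapting:
                self._tally(f"beta_c[{j}]", float(accepted))
        # included selectable terms
        for j in np.flatnonzero(self.eff):
            scale = np.exp(self.ls_v[j])
            prop = st.beta_v[j] + scale * self.rng.normal()
            delta = (prop - st.beta_v[j]) * self.Xv[:, j]
            ll_prop = self._ll(self.eta + delta)
            sd = self._psi(j) * st.sigma
            logr = ll_prop - self.ll - (prop**2 - st.beta_v[j] ** 2) / (2 * sd**2)
            alpha = min(1.0, float(np.exp(min(logr, 0.0))))
            accepted = np.log(self.rng.random()) < logr
            if accepted:
                st.beta_v[j] = prop
                self.eta = self.eta + delta
                self.ll = ll_prop
            self._adapt("v", j, alpha)
            if not self.adapting:
                self._tally(f"beta_v[{j}]", float(accepted))

    def update_inclusion_probs(self):
        st = self.state
        a = np.concatenate([
            np.full(self.n_main, self.priors.a_main),
            np.full(self.n_int, self.priors.a_int),
        ])
        b = np.concatenate([
            np.full(self.n_main, self.priors.b_main),
            np.full(self.n_int, self.priors.b_int),
        ])
        ind = np.concatenate([st.I, st.J]).astype(float)
        st.p = self.rng.beta(a + ind, b + 1.0 - ind)

    def _active(self) -> np.ndarray:
        """Selectable terms whose coefficient is informed by the likelihood."""
        if self.prior_only:
            return np.zeros(self.m, dtype=bool)
        return self.eff.astype(bool)

    def update_variance_components(self):
        st = self.state
        pri = self.priors
        active = self._active()

        def beta_prior_sum(sigma, psi_int, mask):
            if not mask.any():
                return 0.0
            psi = np.where(np.arange(self.m) < self.n_main, pri.psi_main, psi_int)
            sd = psi[mask] * sigma
            b = st.beta_v[mask]
            return float(-0.5 * np.sum((b / sd) ** 2) - np.sum(np.log(sd)))

        if self.chain.sample_sigma:
            u = np.log(st.sigma)
            u_prop = u + np.exp(self.ls_sigma) * self.rng.normal()
            s_prop = float(np.exp(u_prop))
            logr = (
                log_sigma_prior(s_prop, pri) + u_prop
                + beta_prior_sum(s_prop, st.psi_int, active)
                - log_sigma_prior(st.sigma, pri) - u
                - beta_prior_sum(st.sigma, st.psi_int, active)
            )
            alpha = min(1.0, float(np.exp(min(logr, 0.0))))
            accepted = np.log(self.rng.random()) < logr
            if accepted:
                st.sigma = s_prop
            self._adapt("sigma", None, alpha)
            if not self.adapting:
                self._tally("sigma", float(accepted))

        if self.chain.sample_psi_int and self.n_int:
            act_int = active.copy()
            act_int[: self.n_main] = False
            lam = np.log(st.psi_int)
            lam_prop = lam + np.exp(self.ls_psi) * self.rng.normal()

            def lam_target(l):
                val = -0.5 * (l - pri.mu_int) ** 2 / pri.tau_int
                return val + beta_prior_sum(st.sigma, float(np.exp(l)), act_int)

            logr = lam_target(lam_prop) - lam_target(lam)
            alpha = min(1.0, float(np.exp(min(logr, 0.0))))
            accepted = np.log(self.rng.random()) < logr
            if accepted:
                st.psi_int = float(np.exp(lam_prop))
            self._adapt("psi", None, alpha)
            if not self.adapting:
                self._tally("psi_int", float(accepted))

    def refresh_excluded(self):
        """Draw coefficients of likelihood-inactive terms from their prior,
        completing the collapsed variance update."""
        st = self.state
        inactive = ~self._active()
        if inactive.any():
            sd = self._psi_vec()[inactive] * st.sigma
            st.beta_v[inactive] = self.rng.normal(0.0, 1.0, inactive.sum()) * sd
        if self.prior_only:
            st.beta_c = self.rng.normal(0.0, self.priors.fixed_coef_sd, self.n_fixed)

    def sweep(self):
        self.update_indicators()
        self.update_coefficients()
        self.update_inclusion_probs()
        self.update_variance_components()
        self.refresh_excluded()

    def acceptance_rates(self) -> dict[str, float]:
        return {k: (v[0] / v[1] if v[1] else float("nan")) for k, v in self.accept.items()}


@dataclass
class Trace:
    """Retained MCMC samples plus bookkeeping."""

    terms: TermSet
    fixed_names: tuple[str, ...]
    beta_c: np.ndarray       # (R, n_fixed)
    beta_v: np.ndarray       # (R, m)
    I: np.ndarray            # (R, n_main) uint8
    J: np.ndarray            # (R, n_int) uint8
    eff: np.ndarray          # (R, m) uint8
    p: np.ndarray            # (R, m)
    sigma: np.ndarray        # (R,)
    log_psi_int: np.ndarray  # (R,)
    loglik: np.ndarray       # (R,)
    acceptance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.sigma.shape[0]

    @property
    def selectable_names(self) -> tuple[str, ...]:
        return self.terms.selectable_terms

    def inclusion_probabilities(self) -> pd.Series:
        """Posterior inclusion probability (mean effective indicator)."""
        return pd.Series(self.eff.mean(axis=0), index=list(self.selectable_names))

    def model_ids(self) -> list[tuple[str, ...]]:
        names = np.array(self.selectable_names)
        return [tuple(sorted(names[row.astype(bool)])) for row in self.eff]

    def model_frequencies(self) -> pd.Series:
        ids = pd.Series(["+".join(m) for m in self.model_ids()])
        return ids.value_counts(normalize=True)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for i, name in enumerate(self.fixed_names):
            cols[f"beta_c.{name}"] = self.beta_c[:, i]
        sel = self.selectable_names
        for i, name in enumerate(sel):
            cols[f"beta.{name}"] = self.beta_v[:, i]
        for i, name in enumerate(sel):
            cols[f"eff.{name}"] = self.eff[:, i]
        for i, name in enumerate(self.terms.main_terms):
            cols[f"I.{name}"] = self.I[:, i]
        for i, name in enumerate(self.terms.interaction_names):
            cols[f"J.{name}"] = self.J[:, i]
        for i, name in enumerate(sel):
            cols[f"p.{name}"] = self.p[:, i]
        cols["sigma"] = self.sigma
        cols["log_psi_int"] = self.log_psi_int
        cols["loglik"] = self.loglik
        frame = pd.DataFrame(cols)
        frame["model"] = ["+".join(m) for m in self.model_ids()]
        return frame

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.to_frame().to_csv(os.path.join(directory, "trace.csv"), index=False)
        meta = {
            "terms": self.terms.to_config(),
            "fixed_names": list(self.fixed_names),
            "acceptance": {k: float(v) for k, v in self.acceptance.items()},
        }
        with open(os.path.join(directory, "meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, directory) -> "Trace":
        import os

        with open(os.path.join(directory, "meta.yaml")) as fh:
            meta = yaml.safe_load(fh)
        terms = TermSet.from_config(meta["terms"])
        frame = pd.read_csv(os.path.join(directory, "trace.csv"))
        fixed_names = tuple(meta["fixed_names"])
        sel = terms.selectable_terms
        bc_cols = [c for c in frame.columns if c.startswith("beta_c.")]
        return cls(
            terms=terms,
            fixed_names=fixed_names,
            beta_c=frame[bc_cols].to_numpy(float),
            beta_v=frame[[f"beta.{n}" for n in sel]].to_numpy(float),
            I=frame[[f"I.{n}" for n in terms.main_terms]].to_numpy(np.uint8),
            J=frame[[f"J.{n}" for n in terms.interaction_names]].to_numpy(np.uint8),
            eff=frame[[f"eff.{n}" for n in sel]].to_numpy(np.uint8),
            p=frame[[f"p.{n}" for n in sel]].to_numpy(float),
            sigma=frame["sigma"].to_numpy(float),
            log_psi_int=frame["log_psi_int"].to_numpy(float),
            loglik=frame["loglik"].to_numpy(float),
            acceptance=dict(meta.get("acceptance", {})),
        )


def sample_posterior(
    design: DesignMatrix | None,
    outcome,
    terms: TermSet,
    priors: PriorConfig | None = None,
    chain: ChainConfig | None = None,
) -> Trace:
    """Run the full sampler on a prebuilt design matrix."""
    priors = priors or PriorConfig()
    chain = chain or ChainConfig()
    rng = np.random.default_rng(chain.seed)
    if chain.prior_only:
        n_fixed = 0 if design is None else design.fixed().shape[1]
        fixed_names = () if design is None else (
            (("intercept",) if design.has_intercept else ()) + design.fixed_names)
    else:
        if design is None or outcome is None:
            raise ValueError("design and outcome are required unless prior_only")
        n_fixed = design.fixed().shape[1]
        fixed_names = (("intercept",) if design.has_intercept else ()) + design.fixed_names

    state = ChainState.initial(terms, priors, chain, n_fixed)
    smp = _Sampler(state, design, outcome, terms, priors, chain, rng)

    R = chain.n_retained
    m = terms.n_main + terms.n_interaction
    out = Trace(
        terms=terms,
        fixed_names=fixed_names,
        beta_c=np.empty((R, n_fixed)),
        beta_v=np.empty((R, m)),
        I=np.empty((R, terms.n_main), dtype=np.uint8),
        J=np.empty((R, terms.n_interaction), dtype=np.uint8),
        eff=np.empty((R, m), dtype=np.uint8),
        p=np.empty((R, m)),
        sigma=np.empty(R),
        log_psi_int=np.empty(R),
        loglik=np.empty(R),
    )
    start = chain.n_adapt + chain.n_burn
    r = 0
    for t in range(chain.n_iter):
        smp.adapting = t < chain.n_adapt
        smp.sweep()
        if not np.isfinite(smp.ll):
            raise RuntimeError(f"non-finite log-likelihood at iteration {t}")
        if t >= start and (t - start) % chain.thin == 0 and r < R:
            out.beta_c[r] = state.beta_c
            out.beta_v[r] = state.beta_v
            out.I[r] = state.I
            out.J[r] = state.J
            out.eff[r] = smp.eff
            out.p[r] = state.p
            out.sigma[r] = state.sigma
            out.log_psi_int[r] = np.log(state.psi_int)
            out.loglik[r] = smp.ll
            r += 1
    out.acceptance = smp.acceptance_rates()
    return out


def run_chain(
    data: pd.DataFrame | None,
    terms: TermSet,
    priors: PriorConfig | None = None,
    chain: ChainConfig | None = None,
    menopause_coding: str = "dummy",
) -> Trace:
    """Fit the averaged model to a cohort table (column ``outcome`` = 0/1).

    ``data`` may be ``None`` for a prior-only chain.
    """
    chain = chain or ChainConfig()
    if data is None:
        if not chain.prior_only:
            raise ValueError("data may only be omitted for a prior-only chain")
        return sample_posterior(None, None, terms, priors, chain)
    design = build_design(data, terms, menopause_coding=menopause_coding)
    y = data["outcome"].to_numpy(float)
    return sample_posterior(design, y, terms, priors, chain)


# ---------------------------------------------------------------------------
# public single-step kernels (for testing and composition)
# ---------------------------------------------------------------------------

def _one_shot(state, design, outcome, terms, priors, rng, chain=None) -> _Sampler:
    chain = chain or ChainConfig(prior_only=design is None)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    smp = _Sampler(state, design, outcome, terms, priors, chain, rng)
    smp.adapting = False
    return smp


def update_inclusion_probs(state: ChainState, terms: TermSet, priors: PriorConfig, rng) -> np.ndarray:
    """Exact conjugate beta draw of every per-term inclusion probability."""
    smp = _one_shot(state, None, None, terms, priors, rng)
    smp.update_inclusion_probs()
    return state.p


def update_indicators(state, design, outcome, terms, priors, rng, chain=None) -> ChainState:
    """One random-scan Metropolised sweep over all indicators."""
    smp = _one_shot(state, design, outcome, terms, priors, rng, chain)
    smp.update_indicators()
    return state


def update_coefficients(state, design, outcome, terms, priors, rng, chain=None) -> ChainState:
    """One RW-Metropolis sweep over adjustment and included coefficients."""
    smp = _one_shot(state, design, outcome, terms, priors, rng, chain)
    smp.update_coefficients()
    if smp.prior_only:
        smp.refresh_excluded()
    return state


def update_variance_components(state, terms, priors, rng, chain=None,
                               design=None, outcome=None) -> ChainState:
    """One MH update of sigma and psi_int (collapsed over excluded terms),
    followed by the excluded-coefficient refresh."""
    smp = _one_shot(state, design, outcome, terms, priors, rng, chain)
    smp.update_variance_components()
    smp.refresh_excluded()
    return state
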