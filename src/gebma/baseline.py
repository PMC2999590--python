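"""Frequentist comparator: maximum-likelihood logistic regression and
backward stepwise selection by AIC under strong heredity.

Every model carries the adjustment covariates (age, family history,
menopausal status) plus an intercept; the selectable terms are the same
centered columns the averaged model uses. Fitting is IRLS via statsmodels
GLM with Wald standard errors from the observed information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .terms import DesignMatrix, TermSet, heredity_closure, interaction_name

__all__ = ["GlmFit", "fit_logistic", "pointwise_scan", "backward_stepwise_aic", "StepwiseResult"]


@dataclass
class GlmFit:
    """One fitted logistic model."""

    terms: tuple[str, ...]          # selectable terms in the model
    columns: tuple[str, ...]        # all design columns incl. intercept/fixed
    params: pd.Series               # log-odds estimates
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame          # 95% Wald CI on the log-odds scale
    llf: float
    aic: float
    nobs: int

    def odds_ratio(self, term: str) -> tuple[float, float, float, float]:
        """(OR, lo, hi, p) for one column on the odds-ratio scale."""
        lo, hi = self.conf_int.loc[term]
        return (
            float(np.exp(self.params[term])),
            float(np.exp(lo)),
            float(np.exp(hi)),
            float(self.pvalues[term]),
        )


def _design_columns(design: DesignMatrix, terms_subset) -> list[str]:
    cols = (["intercept"] if design.has_intercept else []) + list(design.fixed_names)
    return cols + [t for t in design.selectable_names if t in set(terms_subset)]


def fit_logistic(design: DesignMatrix, outcome, terms_subset=()) -> GlmFit:
    """ML logistic fit of the adjustment block plus a subset of selectable terms.

    Raises on rank deficiency or separation, naming the offending columns.
    """
    cols = _design_columns(design, terms_subset)
    X = design.frame[cols]
    Xm = X.to_numpy(float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j, c in enumerate(cols):
            if np.linalg.matrix_rank(np.delete(Xm, j, axis=1)) == np.linalg.matrix_rank(Xm):
                bad.append(c)
        raise ValueError(f"design is rank deficient; offending columns: {bad or cols}")
    y = np.asarray(outcome, float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(tol=1e-10, maxiter=200)
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
        bad = [c for c, se in res.bse.items() if not np.isfinite(se) or se > 1e3]
        raise ValueError(f"separation suspected; unstable columns: {bad}")
    return GlmFit(
        terms=tuple(t for t in terms_subset),
        columns=tuple(cols),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=res.conf_int(alpha=0.05),
        llf=float(res.llf),
        aic=float(res.aic),
        nobs=int(res.nobs),
    )


def pointwise_scan(design: DesignMatrix, terms: TermSet, outcome) -> pd.DataFrame:
    """One adjusted model per selectable term.

    Mains are fitted alone (plus adjustment covariates); interactions are
    fitted together with both parent main effects. Rows report the focal
    term's Wald OR/CI/p; failures are recorded and the scan continues.
    """
    rows = []
    for name in terms.main_terms:
        try:
            fit = fit_logistic(design, outcome, (name,))
            or_, lo, hi, p = fit.odds_ratio(name)
            rows.append({"term": name, "kind": "main", "model_terms": name,
                         "or": or_, "ci_low": lo, "ci_high": hi, "p": p, "aic": fit.aic,
                         "error": None})
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            rows.append({"term": name, "kind": "main", "error": str(exc)})
    for a, b in terms.interaction_terms:
        name = interaction_name(a, b)
        subset = (a, b, name)
        try:
            fit = fit_logistic(design, outcome, subset)
            or_, lo, hi, p = fit.odds_ratio(name)
            rows.append({"term": name, "kind": "interaction", "model_terms": "+".join(subset),
                         "or": or_, "ci_low": lo, "ci_high": hi, "p": p, "aic": fit.aic,
                         "error": None})
        except Exception as exc:  # noqa: BLE001
            rows.append({"term": name, "kind": "interaction", "error": str(exc)})
    return pd.DataFrame(rows)


@dataclass
class StepwiseResult:
    selected: tuple[str, ...]
    path: pd.DataFrame          # step, removed, aic
    final_fit: GlmFit


def backward_stepwise_aic(design: DesignMatrix, terms: TermSet, outcome,
                          start_terms=None) -> StepwiseResult:
    """Pure backward AIC selection over the selectable terms.

    At each step the single eligible term whose removal most decreases AIC is
    dropped; a main effect is ineligible while any of its interactions
    remains (strong heredity); the adjustment block is never removed. Ties
    break towards the earlier term in canonical order. Stops when no removal
    decreases AIC.
    """
    current = list(design.selectable_names if start_terms is None else start_terms)
    legal, violators = heredity_closure(current, terms)
    if not legal:
        raise ValueError(f"start model violates heredity: {violators}")
    hered = terms.heredity()
    fit = fit_logistic(design, outcome, tuple(current))
    path = [{"step": 0, "removed": None, "aic": fit.aic}]
    step = 0
    while current:
        protected = set()
        for name, (a, b) in hered.items():
            if name in current:
                protected.update((a, b))
        candidates = [t for t in design.selectable_names if t in current and t not in protected]
        best_term, best_fit = None, None
        for t in candidates:  # canonical order: first strict winner kept on ties
            sub = tuple(x for x in current if x != t)
            cand = fit_logistic(design, outcome, sub)
            if cand.aic < fit.aic and (best_fit is None or cand.aic < best_fit.aic):
                best_term, best_fit = t, cand
        if best_term is None:
            break
        current.remove(best_term)
        fit = best_fit
        step += 1
        path.append({"step": step, "removed": best_term, "aic": fit.aic})
    return StepwiseResult(selected=tuple(current), path=pd.DataFrame(path), final_fit=fit)
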