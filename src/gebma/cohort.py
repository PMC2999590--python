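"""Synthetic case-control cohort generation.

The original study cohort (654 breast-cancer cases, 1085 controls from a
German population-based study of smoking-related carcinogen-metabolism genes)
is not publicly deposited, so this module generates cohorts that reproduce
its published marginal structure: genotype category frequencies for six
polymorphisms, age ~ 42.6 +/- 5.7 truncated to the study's age range,
family-history and menopausal-status frequencies, and a zero-inflated,
right-skewed packyears distribution matching mean 6.96 / SD 10.88 among
controls.

Outcomes come from a configurable logistic disease model: a large
superpopulation is generated, case status drawn Bernoulli from the logistic
model, and exactly ``n_cases`` / ``n_controls`` subjects sampled without
replacement (frequency-matched case-control sampling; no individual
matching, mirroring an unconditional analysis adjusted for age).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

from .terms import TermSet, MENOPAUSE_LEVELS

__all__ = [
    "CohortSpec",
    "TrueModel",
    "sample_genotypes",
    "sample_exposure_covariates",
    "assign_outcomes",
    "simulate_cohort",
    "summarize_cohort",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

#: documented CSV column order
COHORT_COLUMNS = (
    "outcome", "age", "famhist", "menopause", "packyears",
    "nat1", "cyp1b1", "nat2", "cyp1a1", "gstt1", "gstm1",
)


def _norm(v):
    v = np.asarray(v, float)
    return tuple(v / v.sum())


#: control-arm genotype category frequencies (allele-count genes carry three
#: categories, binary codings two), normalised to sum exactly to 1
DEFAULT_GENOTYPE_FREQS = {
    "nat1": _norm([0.686, 0.286, 0.029]),     # number of *10 alleles 0/1/2
    "cyp1b1": _norm([0.289, 0.509, 0.202]),   # number of *3 alleles 0/1/2
    "nat2": _norm([0.398, 0.602]),            # slow acetylator = 1
    "cyp1a1": _norm([0.751, 0.249]),          # variant (not *1/*1) = 1
    "gstt1": _norm([0.819, 0.181]),           # deletion = 1
    "gstm1": _norm([0.488, 0.512]),           # deletion = 1
}


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic case-control cohort.

    Defaults reproduce the control-arm marginals of the motivating study.
    ``smoker_prob`` (the never-smoker zero mass of packyears) is not reported
    there and defaults to 0.5; the smoker gamma mean/SD are solved so the
    overall mixture hits the published 6.96 +/- 10.88.
    """

    n_cases: int = 654
    n_controls: int = 1085
    genotype_freqs: dict = field(default_factory=lambda: dict(DEFAULT_GENOTYPE_FREQS))
    age_mean: float = 42.6
    age_sd: float = 5.7
    age_range: tuple[float, float] = (18.0, 50.0)
    famhist_prob: float = 0.052
    menopause_probs: tuple[float, float, float] = (0.806, 0.065, 0.129)  # pre, post, unknown
    smoker_prob: float = 0.5
    packyears_mean_smokers: float = 13.92
    packyears_sd_smokers: float = 11.83
    superpopulation_factor: int = 20
    target_prevalence: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        for gene, probs in self.genotype_freqs.items():
            probs = np.asarray(probs, float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(f"genotype frequencies for {gene!r} outside [0,1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"genotype frequencies for {gene!r} do not sum to 1")
        mp = np.asarray(self.menopause_probs, float)
        if abs(mp.sum() - 1.0) > 1e-9 or np.any(mp < 0):
            raise ValueError("menopause_probs must be a probability vector summing to 1")
        for name in ("famhist_prob", "smoker_prob", "target_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.age_sd <= 0 or self.packyears_sd_smokers <= 0:
            raise ValueError("standard deviations must be positive")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


@dataclass
class TrueModel:
    """Generating logistic disease model.

    ``coefficients`` maps term names (cohort columns, or ``"a:b"`` products
    of two columns) to log-odds per unit on the *raw* scale. ``intercept``
    may be ``None``, in which case it is calibrated by bisection so the
    superpopulation prevalence matches ``CohortSpec.target_prevalence``.
    """

    intercept: float | None = None
    coefficients: dict[str, float] = field(default_factory=dict)

    def validate_against(self, terms: TermSet) -> None:
        """Check interaction coefficients only reference legal term pairs."""
        legal = set(terms.selectable_terms)
        for name in self.coefficients:
            if ":" in name and name not in legal:
                raise ValueError(f"interaction coefficient {name!r} not legal in this universe")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(intercept=cfg.get("intercept"), coefficients=dict(cfg.get("coefficients", {})))


def sample_genotypes(spec: CohortSpec, n: int, rng_seed=None) -> pd.DataFrame:
    """Draw i.i.d. categorical genotype codings for ``n`` subjects."""
    rng = np.random.default_rng(spec.seed if rng_seed is None else rng_seed)
    cols = {}
    for gene, probs in spec.genotype_freqs.items():
        probs = np.asarray(probs, float)
        cols[gene] = rng.choice(len(probs), size=n, p=probs).astype(np.int64)
    return pd.DataFrame(cols)


def sample_exposure_covariates(spec: CohortSpec, n: int, rng_seed=None) -> pd.DataFrame:
    """Draw age, family history, menopausal status and packyears.

    Age is truncated normal on ``spec.age_range``; packyears is a
    zero-inflated gamma: zero with probability ``1 - smoker_prob``, else
    gamma with shape/scale solved from the smoker mean/SD.
    """
    rng = np.random.default_rng(spec.seed if rng_seed is None else rng_seed)
    lo, hi = spec.age_range
    # place the latent normal so the *truncated* mean hits the target
    def trunc_mean(loc):
        a, b = (lo - loc) / spec.age_sd, (hi - loc) / spec.age_sd
        return truncnorm.mean(a, b, loc=loc, scale=spec.age_sd)

    loc_lo, loc_hi = lo, hi + 6 * spec.age_sd
    for _ in range(80):
        mid = 0.5 * (loc_lo + loc_hi)
        if trunc_mean(mid) < spec.age_mean:
            loc_lo = mid
        else:
            loc_hi = mid
    loc = 0.5 * (loc_lo + loc_hi)
    a, b = (lo - loc) / spec.age_sd, (hi - loc) / spec.age_sd
    age = truncnorm.rvs(a, b, loc=loc, scale=spec.age_sd, size=n, random_state=rng)
    famhist = (rng.random(n) < spec.famhist_prob).astype(np.int64)
    menopause = rng.choice(np.array(MENOPAUSE_LEVELS), size=n, p=np.asarray(spec.menopause_probs, float))
    smoker = rng.random(n) < spec.smoker_prob
    packyears = np.zeros(n)
    if smoker.any():
        mu, sd = spec.packyears_mean_smokers, spec.packyears_sd_smokers
        shape = (mu / sd) ** 2
        scale = sd**2 / mu
        packyears[smoker] = rng.gamma(shape, scale, size=int(smoker.sum()))
    return pd.DataFrame(
        {"age": age, "famhist": famhist, "menopause": menopause, "packyears": packyears}
    )


def _linear_predictor(pop: pd.DataFrame, model: TrueModel, intercept: float) -> np.ndarray:
    eta = np.full(len(pop), float(intercept))
    for name, coef in model.coefficients.items():
        if ":" in name:
            a, b = name.split(":")
            col = pop[a].to_numpy(float) * pop[b].to_numpy(float)
        else:
            col = pop[name].to_numpy(float)
        eta += float(coef) * col
    return eta


def _calibrate_intercept(pop, model, target: float) -> float:
    """Bisection on the intercept for a target mean disease probability."""
    eta0 = _linear_predictor(pop, model, 0.0)
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(eta0 + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def assign_outcomes(
    population: pd.DataFrame,
    model: TrueModel,
    spec: CohortSpec,
    rng_seed=None,
) -> pd.DataFrame:
    """Assign Bernoulli-logistic outcomes and sample the case-control cohort.

    Raises if the superpopulation yields too few cases or controls, with a
    hint to raise the superpopulation factor or the intercept.
    """
    rng = np.random.default_rng(spec.seed if rng_seed is None else rng_seed)
    intercept = model.intercept
    if intercept is None:
        intercept = _calibrate_intercept(population, model, spec.target_prevalence)
    eta = _linear_predictor(population, model, intercept)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor in generating model")
    y = rng.random(len(population)) < expit(eta)
    case_idx = np.flatnonzero(y)
    ctrl_idx = np.flatnonzero(~y)
    if len(case_idx) < spec.n_cases or len(ctrl_idx) < spec.n_controls:
        raise ValueError(
            f"superpopulation produced {len(case_idx)} cases / {len(ctrl_idx)} controls, "
            f"need {spec.n_cases}/{spec.n_controls}; increase superpopulation_factor "
            "or adjust the intercept/target prevalence"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, size=spec.n_cases, replace=False),
            rng.choice(ctrl_idx, size=spec.n_controls, replace=False),
        ]
    )
    out = population.iloc[take].reset_index(drop=True)
    out.insert(0, "outcome", np.concatenate(
        [np.ones(spec.n_cases, dtype=np.int64), np.zeros(spec.n_controls, dtype=np.int64)]
    ))
    return out[list(COHORT_COLUMNS)]


def simulate_cohort(
    spec: CohortSpec | None = None,
    model: TrueModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a full synthetic cohort (superpopulation + outcome sampling)."""
    spec = spec or CohortSpec()
    model = model or TrueModel()
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_cov, s_gen, s_out = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    n_super = spec.superpopulation_factor * (spec.n_cases + spec.n_controls)
    pop = pd.concat(
        [
            sample_exposure_covariates(spec, n_super, rng_seed=s_cov),
            sample_genotypes(spec, n_super, rng_seed=s_gen),
        ],
        axis=1,
    )
    return assign_outcomes(pop, model, spec, rng_seed=s_out)


def summarize_cohort(data: pd.DataFrame) -> pd.DataFrame:
    """Per-arm counts, genotype percentages and mean+/-SD covariate summary."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    cases = data[data["outcome"] == 1]
    ctrls = data[data["outcome"] == 0]
    rows = [("n", "", float(len(cases)), float(len(ctrls)))]

    def ms(col):
        return [
            (col, "mean", float(cases[col].mean()), float(ctrls[col].mean())),
            (col, "sd", float(cases[col].std(ddof=1)), float(ctrls[col].std(ddof=1))),
        ]

    rows += ms("age") + ms("packyears")
    rows.append(("famhist", ">=1 (%)",
                 100.0 * float((cases["famhist"] >= 1).mean()),
                 100.0 * float((ctrls["famhist"] >= 1).mean())))
    for lv in MENOPAUSE_LEVELS:
        rows.append(("menopause", lv,
                     100.0 * float((cases["menopause"] == lv).mean()),
                     100.0 * float((ctrls["menopause"] == lv).mean())))
    for gene in ("nat1", "cyp1b1", "nat2", "cyp1a1", "gstt1", "gstm1"):
        if gene not in data.columns:
            continue
        levels = range(int(data[gene].max()) + 1) if len(data[gene]) else []
        for lv in levels:
            rows.append((gene, str(lv),
                         100.0 * float((cases[gene] == lv).mean()),
                         100.0 * float((ctrls[gene] == lv).mean())))
    return pd.DataFrame(rows, columns=["variable", "level", "cases", "controls"])


def write_cohort(data: pd.DataFrame, path) -> None:
    data[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return data
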