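import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gebma.cohort import CohortSpec, TrueModel, simulate_cohort
from gebma.priors import PriorConfig
from gebma.terms import DesignMatrix, TermSet, default_term_set

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def term_set() -> TermSet:
    return default_term_set()


@pytest.fixture(scope="session")
def prior_config() -> PriorConfig:
    return PriorConfig()


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Small null cohort (no genetic or exposure effects) for fast fits."""
    spec = CohortSpec(n_cases=150, n_controls=250, superpopulation_factor=15, seed=5)
    return simulate_cohort(spec, TrueModel(), seed=5)


@pytest.fixture(scope="session")
def study_size_cohort() -> pd.DataFrame:
    """Null cohort at the study's 654/1085 size."""
    return simulate_cohort(CohortSpec(), TrueModel(), seed=17)


def tiny_two_term_problem(seed: int = 42, n: int = 40):
    """Fixed 40-subject dataset over a 2-main-term universe with no
    adjustment block; used by brute-force enumeration oracles."""
    ts = TermSet(fixed_terms=(), main_terms=("a", "b"), interaction_terms=(),
                 pathway_map={}, exposure=None)
    rng = np.random.default_rng(seed)
    xa = rng.normal(size=n)
    xb = rng.normal(size=n)
    xa -= xa.mean()
    xb -= xb.mean()
    eta = 0.9 * xa - 0.6 * xb
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    design = DesignMatrix(
        frame=pd.DataFrame({"a": xa, "b": xb}),
        fixed_names=(), main_names=("a", "b"), interaction_names=(),
        centers={}, terms=ts, has_intercept=False,
    )
    return ts, design, y
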