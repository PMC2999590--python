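"""Candidate-term universe and centered design construction.

The model space is organised around a fixed block of adjustment covariates
``X_c`` (age, family history, menopausal status) that is present in every
model, and a selectable block ``X_v`` of main effects (a single exposure plus
genotyped polymorphisms) and pairwise interactions. Two structural rules
shape the interaction set:

* **strong heredity** — an interaction may enter a model only when both of
  its parent main effects are present;
* **pathway restriction** — gene-gene interactions are only formed between
  genes annotated to the same metabolic pathway.

All design columns are mean-centered; interaction columns are products of the
centered parent columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TermSet",
    "DesignMatrix",
    "build_term_set",
    "default_term_set",
    "build_design",
    "heredity_closure",
    "DEFAULT_GENES",
    "DEFAULT_PATHWAYS",
    "DEFAULT_FIXED_TERMS",
]

#: the six polymorphisms of the default analysis, alphabetical
DEFAULT_GENES = ("cyp1a1", "cyp1b1", "gstm1", "gstt1", "nat1", "nat2")

#: aromatic-amine (AA) and polycyclic-aromatic-hydrocarbon (PAH) pathways
DEFAULT_PATHWAYS = {
    "nat1": "AA",
    "nat2": "AA",
    "cyp1a1": "PAH",
    "cyp1b1": "PAH",
    "gstm1": "PAH",
    "gstt1": "PAH",
}

DEFAULT_EXPOSURE = "packyears"

#: adjustment covariates present in every model (besides the intercept)
DEFAULT_FIXED_TERMS = ("age", "famhist", "menopause")


def interaction_name(a: str, b: str) -> str:
    """Canonical name of the interaction between terms ``a`` and ``b``."""
    return f"{a}:{b}"


@dataclass(frozen=True)
class TermSet:
    """The candidate-term universe with heredity and pathway structure.

    Attributes
    ----------
    fixed_terms
        Adjustment covariates included in every model (raw cohort column
        names; categorical covariates are expanded at design time).
    main_terms
        Selectable main effects, exposure first then genes alphabetically.
    interaction_terms
        Ordered (canonicalised) pairs of parent main-effect names.
    pathway_map
        Gene name -> pathway label.
    exposure
        Name of the exposure main effect, or ``None``.
    """

    fixed_terms: tuple[str, ...]
    main_terms: tuple[str, ...]
    interaction_terms: tuple[tuple[str, str], ...]
    pathway_map: dict[str, str] = field(default_factory=dict)
    exposure: str | None = None

    def __post_init__(self):
        names = list(self.main_terms) + [interaction_name(*p) for p in self.interaction_terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate terms in universe")
        mains = set(self.main_terms)
        for a, b in self.interaction_terms:
            if a not in mains or b not in mains:
                raise ValueError(f"interaction ({a},{b}) has a parent outside main_terms")
            if a != self.exposure and b != self.exposure:
                pa, pb = self.pathway_map.get(a), self.pathway_map.get(b)
                if pa is None or pb is None or pa != pb:
                    raise ValueError(f"gene-gene interaction ({a},{b}) crosses pathways")

    # -- naming helpers -------------------------------------------------
    @property
    def interaction_names(self) -> tuple[str, ...]:
        return tuple(interaction_name(*p) for p in self.interaction_terms)

    @property
    def selectable_terms(self) -> tuple[str, ...]:
        """Canonical ordering: mains, then interactions."""
        return tuple(self.main_terms) + self.interaction_names

    @property
    def n_main(self) -> int:
        return len(self.main_terms)

    @property
    def n_interaction(self) -> int:
        return len(self.interaction_terms)

    def is_interaction(self, term: str) -> bool:
        return term in set(self.interaction_names)

    def parents(self, term: str) -> tuple[str, str]:
        """Parent main effects of an interaction term."""
        for pair in self.interaction_terms:
            if interaction_name(*pair) == term:
                return pair
        raise KeyError(f"{term!r} is not an interaction term")

    def heredity(self) -> dict[str, tuple[str, str]]:
        return {interaction_name(*p): p for p in self.interaction_terms}

    def validate_term(self, term: str) -> None:
        if term not in set(self.selectable_terms):
            raise KeyError(f"unknown selectable term {term!r}")

    # -- serialisation ---------------------------------------------------
    def to_config(self) -> dict:
        return {
            "fixed_terms": list(self.fixed_terms),
            "main_terms": list(self.main_terms),
            "interaction_terms": [list(p) for p in self.interaction_terms],
            "pathway_map": dict(self.pathway_map),
            "exposure": self.exposure,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "TermSet":
        return cls(
            fixed_terms=tuple(cfg["fixed_terms"]),
            main_terms=tuple(cfg["main_terms"]),
            interaction_terms=tuple(tuple(p) for p in cfg["interaction_terms"]),
            pathway_map=dict(cfg.get("pathway_map", {})),
            exposure=cfg.get("exposure"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh)

    @classmethod
    def from_yaml(cls, path) -> "TermSet":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def build_term_set(
    genes=DEFAULT_GENES,
    pathways=DEFAULT_PATHWAYS,
    exposure: str | None = DEFAULT_EXPOSURE,
    fixed_terms=DEFAULT_FIXED_TERMS,
) -> TermSet:
    """Construct the term universe for a set of genes and an exposure.

    Mains are the exposure (if any) followed by the genes alphabetically.
    Interactions are exposure x gene for every gene plus every same-pathway
    gene pair; pairs are canonicalised (exposure first, genes alphabetical)
    and listed lexicographically.
    """
    genes = tuple(sorted(genes))
    for g in genes:
        if g not in pathways:
            raise ValueError(f"gene {g!r} missing from pathway map")
    mains = ((exposure,) if exposure else ()) + genes
    inter: list[tuple[str, str]] = []
    if exposure is not None:
        inter.extend((exposure, g) for g in genes)
    by_path: dict[str, list[str]] = {}
    for g in genes:
        by_path.setdefault(pathways[g], []).append(g)
    gene_pairs: list[tuple[str, str]] = []
    for members in by_path.values():
        gene_pairs.extend(itertools.combinations(sorted(members), 2))
    inter.extend(sorted(gene_pairs))
    return TermSet(
        fixed_terms=tuple(fixed_terms),
        main_terms=mains,
        interaction_terms=tuple(inter),
        pathway_map={g: pathways[g] for g in genes},
        exposure=exposure,
    )


def default_term_set() -> TermSet:
    """The default universe: packyears + 6 genes, 20 selectable terms."""
    return build_term_set()


def heredity_closure(included, terms: TermSet) -> tuple[bool, list[str]]:
    """Check the strong-heredity rule for a set of included terms.

    Returns ``(legal, violators)`` where ``violators`` lists every included
    interaction missing at least one parent main effect.
    """
    included = set(included)
    universe = set(terms.selectable_terms)
    unknown = included - universe
    if unknown:
        raise KeyError(f"unknown terms: {sorted(unknown)}")
    violators = [
        name
        for name, (a, b) in terms.heredity().items()
        if name in included and not (a in included and b in included)
    ]
    return (len(violators) == 0, violators)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

MENOPAUSE_LEVELS = ("pre", "post", "unknown")


@dataclass
class DesignMatrix:
    """Centered design columns aligned with a cohort table.

    ``frame`` holds one column per design term. Fixed-covariate columns and
    main-effect columns are mean-centered (the intercept, when present, is
    not); interaction columns are elementwise products of their centered
    parents. ``centers`` stores the means used so a design for new data can
    be built on the same scale.
    """

    frame: pd.DataFrame
    fixed_names: tuple[str, ...]
    main_names: tuple[str, ...]
    interaction_names: tuple[str, ...]
    centers: dict[str, float]
    terms: TermSet
    has_intercept: bool = True

    @property
    def selectable_names(self) -> tuple[str, ...]:
        return self.main_names + self.interaction_names

    def fixed(self) -> np.ndarray:
        cols = (("intercept",) if self.has_intercept else ()) + self.fixed_names
        return self.frame[list(cols)].to_numpy(float)

    def selectable(self) -> np.ndarray:
        return self.frame[list(self.selectable_names)].to_numpy(float)

    def columns(self, names) -> np.ndarray:
        return self.frame[list(names)].to_numpy(float)


def _encode_fixed(data: pd.DataFrame, terms: TermSet, menopause_coding: str) -> pd.DataFrame:
    out = {}
    for name in terms.fixed_terms:
        if name == "menopause":
            men = data["menopause"].astype(str)
            bad = set(men.unique()) - set(MENOPAUSE_LEVELS)
            if bad:
                raise ValueError(f"unknown menopause levels {sorted(bad)}")
            if menopause_coding == "dummy":
                out["meno_post"] = (men == "post").astype(float)
                out["meno_unknown"] = (men == "unknown").astype(float)
            elif menopause_coding == "ordinal":
                out["menopause"] = men.map({lv: i for i, lv in enumerate(MENOPAUSE_LEVELS)}).astype(float)
            else:
                raise ValueError("menopause_coding must be 'dummy' or 'ordinal'")
        elif name == "famhist":
            # dichotomised: any affected first-degree relative
            out["famhist"] = (pd.to_numeric(data["famhist"]) >= 1).astype(float)
        else:
            col = pd.to_numeric(data[name], errors="coerce")
            if col.isna().any():
                raise ValueError(f"fixed covariate {name!r} is not numeric after encoding")
            out[name] = col.astype(float)
    return pd.DataFrame(out, index=data.index)


def build_design(
    data: pd.DataFrame,
    terms: TermSet,
    centers: dict[str, float] | None = None,
    menopause_coding: str = "dummy",
    recenter_interactions: bool = False,
    add_intercept: bool = True,
) -> DesignMatrix:
    """Build the centered design matrix for a cohort table.

    Parameters
    ----------
    centers
        Column means from a previously built design; pass these to place new
        data on the training scale. When ``None`` the means of ``data`` are
        used (and returned in the result).
    recenter_interactions
        If true, interaction columns are re-centered after the product is
        formed (sensitivity switch; the default keeps the pure product
        structure implied by the heredity logic).
    """
    missing = [t for t in terms.main_terms if t not in data.columns]
    if missing:
        raise ValueError(f"dataset is missing main-effect columns: {missing}")
    fixed = _encode_fixed(data, terms, menopause_coding)
    mains = pd.DataFrame(
        {t: pd.to_numeric(data[t], errors="coerce").astype(float) for t in terms.main_terms},
        index=data.index,
    )
    if mains.isna().any().any():
        bad = [c for c in mains.columns if mains[c].isna().any()]
        raise ValueError(f"non-numeric main-effect columns: {bad}")

    fit_centers = centers is None
    centers = dict(centers) if centers else {}

    def center(col: pd.Series, name: str) -> pd.Series:
        if fit_centers:
            centers[name] = float(col.mean())
        return col - centers[name]

    frame = {}
    if add_intercept:
        frame["intercept"] = pd.Series(1.0, index=data.index)
    for name in fixed.columns:
        frame[name] = center(fixed[name], name)
    for name in mains.columns:
        frame[name] = center(mains[name], name)
    for a, b in terms.interaction_terms:
        name = interaction_name(a, b)
        col = frame[a] * frame[b]
        if recenter_interactions:
            col = center(col, name)
        frame[name] = col

    return DesignMatrix(
        frame=pd.DataFrame(frame),
        fixed_names=tuple(fixed.columns),
        main_names=tuple(terms.main_terms),
        interaction_names=terms.interaction_names,
        centers=centers,
        terms=terms,
        has_intercept=add_intercept,
    )
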