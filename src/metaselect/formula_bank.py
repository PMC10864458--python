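"""Published applicability knowledge: resource formulas and decision rules.

The bank holds 48 linear formulas — one per (algorithm, dataset category,
target) with targets log10 fit time and log10 model memory — estimated on a
large UCI benchmark by correlation screening followed by stepwise
regression.  They predict *orders of magnitude* on the original study
hardware; treat their outputs as relative magnitude estimates for comparing
algorithms, not absolute guarantees.  Memory intercepts near 4–7 are
consistent with log10 bytes.

A small rule set captures the study's domain-conditional applicability
findings (e.g. the C4.5 tree is recommended for medical continuous-variable
datasets with more than 15 variables).  Ratio thresholds printed as
percentages are stored as fractions to match the metafeature scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .benchmark import ALGORITHM_ORDER, AlgorithmId
from .data_model import DatasetCategory, DomainTag
from .metafeatures import METAFEATURE_NAMES, MetafeatureVector

__all__ = [
    "LinearFormula",
    "FormulaBank",
    "ApplicabilityRule",
    "Verdict",
    "load_formula_bank",
    "evaluate_formula",
    "predict_resource_magnitudes",
    "applicable_rules",
    "APPLICABILITY_RULES",
]


@dataclass(frozen=True)
class LinearFormula:
    """One linear magnitude-prediction formula."""

    algorithm: AlgorithmId
    category: DatasetCategory
    target: str  # "time" | "memory"
    intercept: float
    terms: tuple[tuple[str, float], ...]
    equation: int  # printed equation number, for provenance
    entropy_base: float = 2.0  # base assumed for E_C / ME_V / MME_CV terms

    def __post_init__(self) -> None:
        for name, _ in self.terms:
            if name not in METAFEATURE_NAMES:
                raise ValueError(f"unknown metafeature {name!r} in formula")


class FormulaBank:
    """The 48 formulas keyed by (algorithm, category, target)."""

    def __init__(self, formulas: Sequence[LinearFormula]):
        self._by_key: dict[tuple, LinearFormula] = {}
        for f in formulas:
            key = (f.algorithm, f.category, f.target)
            if key in self._by_key:
                raise ValueError(f"duplicate formula key {key}")
            self._by_key[key] = f

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, algorithm: AlgorithmId, category: DatasetCategory,
            target: str) -> LinearFormula:
        return self._by_key[(algorithm, category, target)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self:
            rows.append({"equation": f.equation, "algorithm": f.algorithm.value,
                         "category": f.category.value, "target": f.target,
                         "term": "intercept", "coefficient": f.intercept})
            for name, coef in f.terms:
                rows.append({"equation": f.equation,
                             "algorithm": f.algorithm.value,
                             "category": f.category.value, "target": f.target,
                             "term": name, "coefficient": coef})
        return pd.DataFrame(rows)


def load_formula_bank() -> FormulaBank:
    """Load the shipped 48-formula bank and check its integrity."""
    with resources.files("metaselect.data").joinpath("formula_bank.csv").open() as fh:
        table = pd.read_csv(fh)
    formulas = []
    for (eq, alg, cat, target), grp in table.groupby(
        ["equation", "algorithm", "category", "target"], sort=True
    ):
        inter = grp.loc[grp["term"] == "intercept", "coefficient"]
        if len(inter) != 1:
            raise ValueError(f"equation {eq}: expected exactly one intercept")
        terms = tuple(
            (row["term"], float(row["coefficient"]))
            for _, row in grp.iterrows() if row["term"] != "intercept"
        )
        formulas.append(LinearFormula(
            algorithm=AlgorithmId(alg), category=DatasetCategory(cat),
            target=target, intercept=float(inter.iloc[0]), terms=terms,
            equation=int(eq),
        ))
    bank = FormulaBank(formulas)
    if len(bank) != 48:
        raise ValueError(f"formula bank holds {len(bank)} formulas, expected 48")
    return bank


def evaluate_formula(formula: LinearFormula, mf: MetafeatureVector) -> float:
    """intercept + Σ coefficient × metafeature value.

    Raises if a referenced metafeature is flagged ineligible or non-finite.
    """
    import math

    total = formula.intercept
    for name, coef in formula.terms:
        if name in mf.flags:
            raise ValueError(
                f"metafeature {name!r} is flagged ({mf.flags[name]}); "
                f"formula for {formula.algorithm.value} cannot be evaluated"
            )
        value = mf[name]
        if not math.isfinite(value):
            raise ValueError(f"metafeature {name!r} is not finite")
        total += coef * value
    return float(total)


def predict_resource_magnitudes(
    mf: MetafeatureVector, category: DatasetCategory,
    bank: FormulaBank | None = None,
) -> pd.DataFrame:
    """Per-algorithm predicted log10 time and log10 memory for one dataset."""
    bank = bank or load_formula_bank()
    rows = []
    for alg in ALGORITHM_ORDER:
        rows.append({
            "algorithm": alg.value,
            "log10_time": evaluate_formula(bank.get(alg, category, "time"), mf),
            "log10_memory": evaluate_formula(bank.get(alg, category, "memory"), mf),
        })
    return pd.DataFrame(rows).set_index("algorithm")


class Verdict(enum.Enum):
    RECOMMENDED = "recommended"
    CONSIDERED = "considered"


_COMPARATORS = {
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
}


@dataclass(frozen=True)
class ApplicabilityRule:
    """A domain-conditional applicability finding.

    ``predicate`` is a conjunction of (metafeature, comparator, threshold)
    clauses; an empty predicate is an advisory that fires on domain scope
    alone.  Thresholds are stored exactly as published (percentages converted
    to fractions).
    """

    algorithm: AlgorithmId
    category: DatasetCategory
    domain_scope: tuple[DomainTag, ...] | None  # None = any domain
    predicate: tuple[tuple[str, str, float], ...]
    verdict: Verdict
    note: str = ""

    def fires(self, mf: MetafeatureVector) -> bool:
        if self.domain_scope is not None and mf.field_label not in self.domain_scope:
            return False
        for name, op, threshold in self.predicate:
            if not _COMPARATORS[op](mf[name], threshold):
                return False
        return True


APPLICABILITY_RULES: tuple[ApplicabilityRule, ...] = (
    ApplicabilityRule(
        AlgorithmId.AB, DatasetCategory.MIXED, (DomainTag.MEDICAL,),
        (("R_discrete", "<", 0.7778),), Verdict.RECOMMENDED,
        "AdaBoost suits medical mixed-variable datasets whose discrete "
        "variable ratio is below 77.78%",
    ),
    ApplicabilityRule(
        AlgorithmId.NB, DatasetCategory.MIXED, None,
        (("NSR", ">", -38.7407),), Verdict.RECOMMENDED,
        "Naive Bayes suits mixed-variable datasets with noise-signal ratio "
        "above -38.7407 (threshold stored as published; nonnegative under "
        "the default histogram entropy estimator, so the clause is then "
        "always met)",
    ),
    ApplicabilityRule(
        AlgorithmId.NB, DatasetCategory.DISCRETE,
        (DomainTag.MEDICAL, DomainTag.BIOLOGY),
        (), Verdict.RECOMMENDED,
        "Naive Bayes performs markedly better on biomedical discrete-variable "
        "datasets than on general-field ones (domain advisory, no numeric "
        "threshold published)",
    ),
    ApplicabilityRule(
        AlgorithmId.C45, DatasetCategory.CONTINUOUS, (DomainTag.MEDICAL,),
        (("P", ">", 15.0),), Verdict.RECOMMENDED,
        "The C4.5 tree is recommended for medical continuous-variable "
        "datasets with more than 15 variables",
    ),
    ApplicabilityRule(
        AlgorithmId.SVM, DatasetCategory.CONTINUOUS, (DomainTag.MEDICAL,),
        (("Var", "<=", 4.5815),), Verdict.CONSIDERED,
        "SVM can be considered for medical continuous-variable datasets with "
        "mean attribute variance at most 4.5815",
    ),
    ApplicabilityRule(
        AlgorithmId.RF, DatasetCategory.CONTINUOUS, (DomainTag.MEDICAL,),
        (("E_C", ">", 0.2383), ("Geomean", "<=", 0.2241)), Verdict.CONSIDERED,
        "Random forest is considered for medical continuous-variable datasets "
        "with class entropy above 0.2383 and geometric mean at most 0.2241",
    ),
)


def applicable_rules(
    mf: MetafeatureVector, category: DatasetCategory,
    rules: Sequence[ApplicabilityRule] = APPLICABILITY_RULES,
) -> list[tuple[AlgorithmId, Verdict, ApplicabilityRule]]:
    """All stored rules for ``category`` that fire on this metafeature vector."""
    fired = []
    for rule in rules:
        if rule.category is category and rule.fires(mf):
            fired.append((rule.algorithm, rule.verdict, rule))
    return fired
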