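"""Domain-by-label contingency tables and the R×C chi-square test.

For each algorithm, datasets are cross-tabulated by domain (medical /
biology / general) against recommendation label (Y / M / No) and tested for
independence with the R×C chi-square statistic in its marginal-product form

    chi2 = n * ( sum_ij  A_ij^2 / (n_Ri * n_Cj)  -  1 )

which is algebraically identical to the classical Pearson
sum((O − E)^2 / E) with E_ij = n_Ri * n_Cj / n.  A significant statistic
means the algorithm's recommendation pattern differs between fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DomainTag
from .labeling import ApplicabilityLabel

__all__ = ["ContingencyTable", "build_contingency", "chi_square_rc",
           "significance", "domain_difference_report"]

logger = logging.getLogger(__name__)

DOMAIN_ORDER = (DomainTag.MEDICAL, DomainTag.BIOLOGY, DomainTag.GENERAL)
LABEL_ORDER = (ApplicabilityLabel.Y, ApplicabilityLabel.M, ApplicabilityLabel.NO)


@dataclass
class ContingencyTable:
    """R×C count table with fixed row (domain) and column (label) order."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def expected(self) -> np.ndarray:
        return np.outer(self.row_marginals, self.col_marginals) / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[r.value for r in self.row_labels],
            columns=[c.value for c in self.col_labels],
        )


def build_contingency(
    labels: dict[str, ApplicabilityLabel],
    domains: dict[str, DomainTag],
) -> ContingencyTable:
    """Cross-tabulate per-dataset labels against dataset domains.

    ``labels`` maps dataset name → label for one algorithm; ``domains`` maps
    dataset name → domain tag.  Every labeled dataset must have a domain.
    """
    if not labels:
        raise ValueError("no labeled datasets")
    counts = np.zeros((len(DOMAIN_ORDER), len(LABEL_ORDER)), dtype=int)
    row = {d: i for i, d in enumerate(DOMAIN_ORDER)}
    col = {l: j for j, l in enumerate(LABEL_ORDER)}
    for name, label in labels.items():
        if name not in domains:
            raise ValueError(f"dataset {name!r} has no domain tag")
        counts[row[domains[name]], col[label]] += 1
    return ContingencyTable(DOMAIN_ORDER, LABEL_ORDER, counts)


def chi_square_rc(table: ContingencyTable) -> float:
    """R×C chi-square in marginal-product form; requires positive marginals.

    An expected count below 5 triggers a logged warning (small-sample
    caution), not an error.
    """
    r = table.row_marginals
    c = table.col_marginals
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero row or column marginal: statistic undefined")
    if (table.expected() < 5).any():
        logger.warning(
            "expected count < 5 in contingency table; chi-square approximation "
            "may be poor"
        )
    a = table.counts.astype(float)
    return float(table.n * ((a**2 / np.outer(r, c)).sum() - 1.0))


def significance(
    chi2: float, rows: int, cols: int, alpha: float = 0.05
) -> bool:
    """True ("different") iff chi2 exceeds the upper-alpha chi-square
    quantile at (rows−1)(cols−1) degrees of freedom."""
    if rows < 2 or cols < 2:
        raise ValueError("need at least a 2x2 table")
    df = (rows - 1) * (cols - 1)
    return bool(chi2 > stats.chi2.ppf(1 - alpha, df))


def domain_difference_report(
    tables: dict[str, ContingencyTable], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-algorithm chi-square values and difference verdicts."""
    rows = []
    for name, table in tables.items():
        chi2 = chi_square_rc(table)
        diff = significance(chi2, *table.counts.shape, alpha=alpha)
        rows.append({"algorithm": name, "chi2": chi2,
                     "different": "Yes" if diff else "No"})
    return pd.DataFrame(rows)
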