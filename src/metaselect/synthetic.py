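"""Synthetic classification tables and meta-datasets with known structure.

:func:`generate_base_dataset` emulates UCI-style classification tables with
controllable characteristics: Dirichlet class priors, class-conditional
Gaussian continuous attributes with an equicorrelation structure and a
class-separation offset, discrete attributes whose dependence on the class
interpolates between independence and determinism, and MCAR missingness.
Because every knob maps to a measurable metafeature (priors → E_C,
dependence → MME_CV, correlation → MAr), generated data doubles as ground
truth for the characterization code.

:func:`generate_meta_dataset` samples metafeature vectors from documented
ranges and labels them with a planted applicability rule (optionally
noise-flipped) — the test bed for the meta-learners.

The module also exposes verbatim transcriptions of two published summary
tables used as worked-example fixtures: the per-algorithm modeling
completed/failed counts over 293 UCI sub-datasets, and the 3×3
domain-by-label contingency table of the LR algorithm on discrete-variable
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contingency import DOMAIN_ORDER, LABEL_ORDER, ContingencyTable
from .data_model import DomainTag, TabularDataset, VariableKind
from .meta_learner import MetaDataset

__all__ = [
    "BaseDatasetSpec",
    "generate_base_dataset",
    "generate_meta_dataset",
    "META_SAMPLING_RANGES",
    "fixture_table1",
    "fixture_table2",
]


@dataclass
class BaseDatasetSpec:
    """Generation recipe for one synthetic classification table.

    class_prior_concentration is the symmetric Dirichlet concentration for
    the class priors (large → balanced classes, high class entropy).
    class_separation is the between-class mean offset of the continuous
    attributes in within-class standard deviations.  attribute_correlation
    is the common pairwise correlation of the continuous block (must keep
    the equicorrelation matrix positive definite).
    attribute_class_dependence in [0, 1] mixes a class-determined discrete
    level (probability = dependence) with a uniform level, which makes the
    attribute–class mutual information increase monotonically in the knob.
    missing_rate applies an MCAR mask over attribute cells.
    """

    n_rows: int = 500
    n_continuous: int = 4
    n_discrete: int = 2
    n_binary: int = 1
    n_classes: int = 3
    class_prior_concentration: float = 10.0
    class_separation: float = 1.0
    attribute_correlation: float = 0.0
    attribute_class_dependence: float = 0.5
    missing_rate: float = 0.0
    domain: DomainTag = DomainTag.MEDICAL
    n_discrete_levels: int = 4
    continuous_offset: float = 0.0  # shift continuous attributes, e.g. to
    # emulate strictly positive measurements (lab values, counts)
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_classes < 2:
            raise ValueError("need at least one row and two classes")
        if self.n_continuous + self.n_discrete + self.n_binary < 1:
            raise ValueError("need at least one attribute")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        if not 0 <= self.attribute_class_dependence <= 1:
            raise ValueError("attribute_class_dependence must be in [0,1]")
        d = self.n_continuous
        if d > 1 and not -1.0 / (d - 1) < self.attribute_correlation < 1.0:
            raise ValueError(
                f"correlation {self.attribute_correlation} makes the "
                f"{d}-variable equicorrelation matrix non-positive-definite"
            )


def generate_base_dataset(spec: BaseDatasetSpec, seed: int = 0) -> TabularDataset:
    """Draw one classification table per the spec; reproducible from seed."""
    rng = np.random.default_rng(seed)
    k = spec.n_classes
    priors = rng.dirichlet(np.full(k, spec.class_prior_concentration))
    y = rng.choice(k, size=spec.n_rows, p=priors)
    # guarantee every class occurs so the label vector is usable downstream
    for c in range(k):
        if (y == c).sum() == 0:
            y[rng.integers(spec.n_rows)] = c

    columns: dict[str, np.ndarray] = {}
    kinds: list[VariableKind] = []

    if spec.n_continuous:
        d = spec.n_continuous
        rho = spec.attribute_correlation
        cov = np.full((d, d), rho) + np.eye(d) * (1 - rho)
        means = rng.normal(0, 1, size=(k, d))
        means = means / max(np.linalg.norm(means, axis=1).max(), 1e-12)
        means = means * spec.class_separation
        z = rng.multivariate_normal(np.zeros(d), cov, size=spec.n_rows,
                                    method="cholesky")
        x = z + means[y] + spec.continuous_offset
        for j in range(d):
            columns[f"cont_{j}"] = x[:, j]
            kinds.append(VariableKind.CONTINUOUS)

    dep = spec.attribute_class_dependence
    for j in range(spec.n_discrete):
        levels = spec.n_discrete_levels
        determined = (y + j) % levels
        uniform = rng.integers(levels, size=spec.n_rows)
        use_class = rng.random(spec.n_rows) < dep
        columns[f"disc_{j}"] = np.where(use_class, determined, uniform).astype(float)
        kinds.append(VariableKind.DISCRETE)

    for j in range(spec.n_binary):
        determined = (y + j) % 2
        uniform = rng.integers(2, size=spec.n_rows)
        use_class = rng.random(spec.n_rows) < dep
        columns[f"bin_{j}"] = np.where(use_class, determined, uniform).astype(float)
        kinds.append(VariableKind.BINARY)

    frame = pd.DataFrame(columns)
    if spec.missing_rate > 0:
        mask = rng.random(frame.shape) < spec.missing_rate
        frame = frame.mask(mask)
    raw_missing = float(frame.isna().to_numpy().mean())

    return TabularDataset(
        name=spec.name,
        frame=frame,
        kinds=kinds,
        class_labels=pd.Series([f"class_{c}" for c in y]),
        domain=spec.domain,
        raw_missing_ratio=raw_missing,
    )


#: Sampling ranges for planted-rule meta-datasets: plausible spans of each
#: indicator over preprocessed UCI-style tables.
META_SAMPLING_RANGES: dict[str, tuple[float, float]] = {
    "P": (1, 100),
    "N": (30, 20000),
    "N_class": (2, 10),
    "R_largest": (0.2, 0.95),
    "R_least": (0.005, 0.5),
    "R_binary": (0.0, 1.0),
    "R_discrete": (0.0, 1.0),
    "R_continuous": (0.0, 1.0),
    "R_missing": (0.0, 0.3),
    "Geomean": (0.0, 10.0),
    "Harmean": (0.0, 10.0),
    "Trimean": (-5.0, 20.0),
    "Prctile": (-5.0, 50.0),
    "MAD": (0.0, 10.0),
    "Var": (0.0, 25.0),
    "Std": (0.0, 5.0),
    "MAr": (0.0, 1.0),
    "IQR": (0.0, 10.0),
    "D": (-5.0, 20.0),
    "Skewness": (-3.0, 3.0),
    "Kurtosis": (1.0, 10.0),
    "ME_V": (0.0, 4.0),
    "E_C": (0.0, 3.3),
    "MME_CV": (0.0, 2.0),
    "ENV": (1.0, 50.0),
    "NSR": (0.0, 30.0),
}


def generate_meta_dataset(
    predicate,
    n: int,
    label_noise: float = 0.0,
    seed: int = 0,
    *,
    features: list[str] | None = None,
    domains: bool = True,
) -> MetaDataset:
    """Sample metafeature rows and label them with a planted rule.

    ``predicate`` is a callable row → bool, or a conjunction given as a list
    of (feature, comparator, threshold) with comparators <, <=, >, >=.
    ``label_noise`` flips each binary label independently.  Rows draw each
    feature uniformly from :data:`META_SAMPLING_RANGES`; ``domains`` adds a
    categorical ``field_label`` column.
    """
    rng = np.random.default_rng(seed)
    names = features if features is not None else list(META_SAMPLING_RANGES)
    unknown = [f for f in names if f not in META_SAMPLING_RANGES]
    if unknown:
        raise ValueError(f"unknown metafeatures {unknown}")
    data = {
        f: rng.uniform(*META_SAMPLING_RANGES[f], size=n) for f in names
    }
    for f in ("P", "N", "N_class"):
        if f in data:
            data[f] = np.round(data[f])
    X = pd.DataFrame(data)
    if domains:
        X["field_label"] = rng.choice(
            [d.value for d in DOMAIN_ORDER], size=n
        )

    if callable(predicate):
        labels = X.apply(predicate, axis=1).astype(int).to_numpy()
    else:
        ops = {"<": np.less, "<=": np.less_equal,
               ">": np.greater, ">=": np.greater_equal}
        unknown = [f for f, _, _ in predicate if f not in X.columns]
        if unknown:
            raise ValueError(f"predicate references unknown features {unknown}")
        labels = np.ones(n, dtype=bool)
        for feat, op, thr in predicate:
            labels &= ops[op](X[feat].to_numpy(), thr)
        labels = labels.astype(int)

    if label_noise > 0:
        flip = rng.random(n) < label_noise
        labels = np.where(flip, 1 - labels, labels)

    return MetaDataset(features=X, target=pd.Series(labels))


# ---------------------------------------------------------------------------
# Published-table fixtures (verbatim transcriptions)
# ---------------------------------------------------------------------------

def fixture_table1() -> pd.DataFrame:
    """Modeling completed/failed counts of the 8 algorithms over 293 UCI
    sub-datasets, by dataset category, plus the total-failed column."""
    cols = ["mixed_completed", "mixed_failed", "discrete_completed",
            "discrete_failed", "continuous_completed", "continuous_failed",
            "total_failed"]
    rows = {
        "LR":   (93, 9, 29, 5, 138, 19, 33),
        "C4.5": (101, 1, 34, 0, 157, 0, 1),
        "SVM":  (101, 1, 33, 1, 157, 0, 2),
        "AB":   (96, 6, 32, 2, 153, 4, 12),
        "kNN":  (101, 1, 33, 1, 157, 0, 2),
        "NB":   (102, 0, 34, 0, 157, 0, 0),
        "RF":   (95, 7, 33, 1, 152, 5, 13),
        "BP":   (68, 34, 25, 9, 133, 24, 67),
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def fixture_table2() -> ContingencyTable:
    """LR recommendation labels by domain on the 34 discrete-variable
    datasets: rows medical/biology/general, columns Y/M/No."""
    return ContingencyTable(
        row_labels=DOMAIN_ORDER,
        col_labels=LABEL_ORDER,
        counts=np.array([[1, 2, 2], [3, 3, 2], [3, 5, 13]]),
    )


def fixture_table2_assignments() -> tuple[dict, dict]:
    """Per-dataset (label, domain) maps that reproduce the published LR
    contingency table when cross-tabulated; dataset names are synthetic."""
    table = fixture_table2()
    labels, domains = {}, {}
    i = 0
    for r, dom in enumerate(table.row_labels):
        for c, lab in enumerate(table.col_labels):
            for _ in range(int(table.counts[r, c])):
                name = f"ds{i:02d}"
                labels[name] = lab
                domains[name] = dom
                i += 1
    return labels, domains
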