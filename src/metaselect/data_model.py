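"""Tabular dataset container, readers, and preprocessing.

A :class:`TabularDataset` bundles an attribute matrix (with missing-value
sentinels), per-column variable kinds, a class-label vector and a domain tag
(medical / biology / general).  Preprocessing follows a deliberately minimal
policy: attributes missing more than a cutoff fraction of their values are
dropped, then any remaining incomplete rows are removed.  No imputation is
performed — medical records vary strongly between individuals and filled-in
values would distort the dataset characteristics the rest of the package
measures.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableKind",
    "DomainTag",
    "DatasetCategory",
    "TabularDataset",
    "SchemaError",
    "DegenerateDatasetError",
    "read_table",
    "read_arff",
    "infer_variable_kinds",
    "drop_sparse_attributes",
    "drop_incomplete_rows",
    "preprocess",
    "dataset_category",
    "DEFAULT_MISSING_SENTINELS",
]

#: Cell values treated as missing when reading delimited text.
DEFAULT_MISSING_SENTINELS = ("", "?", "NA")


class VariableKind(enum.Enum):
    """Kind of an attribute column.

    ``BINARY`` is a sub-kind of ``DISCRETE`` for ratio accounting: a binary
    column counts toward both the binary and the discrete variable ratio, so
    R_discrete + R_continuous = 1.
    """

    BINARY = "binary"
    DISCRETE = "discrete"
    CONTINUOUS = "continuous"

    @property
    def is_discrete(self) -> bool:
        return self in (VariableKind.BINARY, VariableKind.DISCRETE)


class DomainTag(enum.Enum):
    """Application field a dataset originates from."""

    MEDICAL = "medical"
    BIOLOGY = "biology"
    GENERAL = "general"


class DatasetCategory(enum.Enum):
    """Attribute-composition category of a dataset.

    ``CONTINUOUS`` iff every attribute is continuous, ``DISCRETE`` iff every
    attribute is discrete (binary included), ``MIXED`` otherwise.
    """

    MIXED = "mixed"
    DISCRETE = "discrete"
    CONTINUOUS = "continuous"


class SchemaError(ValueError):
    """The schema sidecar does not match the data file."""


class DegenerateDatasetError(ValueError):
    """Preprocessing removed every attribute or every row."""


@dataclass
class TabularDataset:
    """A classification dataset: attributes, kinds, class labels, domain.

    Parameters
    ----------
    name
        Identifier used in performance records and artifacts.
    frame
        N×P attribute matrix.  Missing cells are ``NaN`` (numeric columns)
        or ``None``/``NaN`` (object columns).
    kinds
        One :class:`VariableKind` per attribute column, in column order.
    class_labels
        Length-N categorical vector; never missing.
    domain
        The dataset's :class:`DomainTag`.
    raw_missing_ratio
        Fraction of missing attribute cells measured when the data was
        loaded, before any preprocessing (after preprocessing it would be
        identically zero, so the loaded value is what R_missing reports).
    provenance
        Log of preprocessing actions (dropped columns/rows).
    """

    name: str
    frame: pd.DataFrame
    kinds: list[VariableKind]
    class_labels: pd.Series
    domain: DomainTag
    raw_missing_ratio: float = 0.0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.shape[1] != len(self.kinds):
            raise ValueError(
                f"{self.frame.shape[1]} columns but {len(self.kinds)} kinds"
            )
        if len(self.class_labels) != len(self.frame):
            raise ValueError("class_labels length does not match row count")
        if self.class_labels.isna().any():
            raise ValueError("class labels must not be missing")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def n_attributes(self) -> int:
        return self.frame.shape[1]

    @property
    def columns(self) -> list[tuple[str, VariableKind]]:
        return list(zip(self.frame.columns, self.kinds))

    def kind_of(self, column: str) -> VariableKind:
        return self.kinds[list(self.frame.columns).index(column)]

    def missing_mask(self) -> pd.DataFrame:
        return self.frame.isna()

    def copy(self) -> "TabularDataset":
        return replace(
            self,
            frame=self.frame.copy(),
            kinds=list(self.kinds),
            class_labels=self.class_labels.copy(),
            provenance=list(self.provenance),
        )


def _coerce_numeric(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert columns that parse fully as numbers; leave the rest as text."""
    out = {}
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        # accept the conversion only where non-missing cells all parsed
        if converted.isna().equals(frame[col].isna()):
            out[col] = converted
        else:
            out[col] = frame[col]
    return pd.DataFrame(out, index=frame.index)


def read_table(
    path: str | Path,
    schema: dict | str | Path,
    *,
    delimiter: str = ",",
    missing_sentinels: Sequence[str] = DEFAULT_MISSING_SENTINELS,
) -> TabularDataset:
    """Read a delimited text file plus a schema sidecar into a dataset.

    The schema (a mapping, or a path to a YAML file) declares::

        columns: [{name: age, kind: continuous}, ...]
        class: diagnosis
        domain: medical

    Column kinds may be omitted (``kind`` key absent), in which case
    :func:`infer_variable_kinds` fills them in.
    """
    path = Path(path)
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise SchemaError("schema must be a mapping")

    raw = pd.read_csv(
        path,
        sep=delimiter,
        na_values=list(missing_sentinels),
        keep_default_na=False,
        skipinitialspace=True,
        dtype=object,
    )
    if raw.empty or raw.shape[1] == 0:
        raise SchemaError(f"{path} contains no data")

    declared = {c["name"]: c.get("kind") for c in schema.get("columns", [])}
    class_col = schema.get("class")
    if class_col is None:
        raise SchemaError("schema must name the class column")
    for col in raw.columns:
        if col != class_col and col not in declared:
            raise SchemaError(f"column {col!r} missing from schema")
    for col in declared:
        if col not in raw.columns:
            raise SchemaError(f"schema column {col!r} not found in {path}")
    if class_col not in raw.columns:
        raise SchemaError(f"class column {class_col!r} not found in {path}")

    domain = DomainTag(schema.get("domain", "general"))
    labels = raw[class_col]
    if labels.isna().any():
        raise SchemaError("class column contains missing values")
    attrs = _coerce_numeric(raw.drop(columns=[class_col]))

    raw_missing = float(attrs.isna().to_numpy().mean()) if attrs.size else 0.0

    kinds: list[VariableKind] = []
    needs_inference = False
    for col in attrs.columns:
        k = declared.get(col)
        if k is None:
            needs_inference = True
            kinds.append(VariableKind.CONTINUOUS)  # placeholder
        else:
            kinds.append(VariableKind(k))

    ds = TabularDataset(
        name=path.stem,
        frame=attrs,
        kinds=kinds,
        class_labels=labels.reset_index(drop=True),
        domain=domain,
        raw_missing_ratio=raw_missing,
    )
    if needs_inference:
        inferred = infer_variable_kinds(ds)
        ds.kinds = [
            VariableKind(declared[c]) if declared.get(c) else inferred[i]
            for i, c in enumerate(attrs.columns)
        ]
    return ds


def read_arff(path: str | Path, *, domain: DomainTag | str = DomainTag.GENERAL,
              class_column: str | None = None) -> TabularDataset:
    """Read an ARFF file.

    Nominal attributes map to discrete (two levels → binary), numeric to
    continuous.  The class column defaults to the last attribute, the ARFF
    convention.
    """
    from scipy.io import arff as scipy_arff

    data, meta = scipy_arff.loadarff(str(path))
    frame = pd.DataFrame(data)
    # scipy returns nominal values as bytes
    for col in frame.columns:
        if frame[col].dtype == object:
            frame[col] = frame[col].str.decode("utf-8")
            frame[col] = frame[col].replace("?", np.nan)

    class_col = class_column or frame.columns[-1]
    labels = frame[class_col]
    if labels.isna().any():
        raise SchemaError("class column contains missing values")
    attrs = frame.drop(columns=[class_col])

    kinds = []
    for col in attrs.columns:
        if meta[col][0] == "nominal":
            levels = meta[col][1]
            kinds.append(
                VariableKind.BINARY if len(levels) == 2 else VariableKind.DISCRETE
            )
        else:
            kinds.append(VariableKind.CONTINUOUS)

    return TabularDataset(
        name=Path(path).stem,
        frame=attrs,
        kinds=kinds,
        class_labels=labels.reset_index(drop=True),
        domain=DomainTag(domain) if isinstance(domain, str) else domain,
        raw_missing_ratio=float(attrs.isna().to_numpy().mean()) if attrs.size else 0.0,
    )


def infer_variable_kinds(
    dataset: TabularDataset, max_discrete_cardinality: int = 10
) -> list[VariableKind]:
    """Infer per-column kinds from the data.

    Exactly two distinct non-missing values → binary; non-numeric columns or
    numeric columns with at most ``max_discrete_cardinality`` distinct values
    → discrete; anything else → continuous.  A constant column is degenerate
    but kept, as discrete.
    """
    kinds = []
    for col in dataset.frame.columns:
        values = dataset.frame[col].dropna()
        n_distinct = values.nunique()
        numeric = pd.api.types.is_numeric_dtype(values)
        if n_distinct == 2:
            kinds.append(VariableKind.BINARY)
        elif not numeric or n_distinct <= max_discrete_cardinality:
            kinds.append(VariableKind.DISCRETE)
        else:
            kinds.append(VariableKind.CONTINUOUS)
    return kinds


def drop_sparse_attributes(
    dataset: TabularDataset, threshold: float = 0.30
) -> TabularDataset:
    """Remove attributes whose missing fraction strictly exceeds ``threshold``.

    The cutoff exists so that removing incomplete rows afterwards does not
    slash the sample size because of a single badly-collected attribute.
    A column at exactly the threshold is retained (strict inequality).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    frac = dataset.frame.isna().mean()
    keep = [c for c in dataset.frame.columns if frac[c] <= threshold]
    dropped = [c for c in dataset.frame.columns if frac[c] > threshold]
    if not keep:
        raise DegenerateDatasetError(
            f"{dataset.name}: all attributes exceed missing threshold {threshold}"
        )
    out = dataset.copy()
    out.frame = out.frame[keep]
    out.kinds = [k for c, k in dataset.columns if c in set(keep)]
    if dropped:
        out.provenance.append(
            f"dropped attributes >{threshold:.0%} missing: {', '.join(dropped)}"
        )
    return out


def drop_incomplete_rows(dataset: TabularDataset) -> TabularDataset:
    """Remove every row with at least one missing attribute cell."""
    complete = ~dataset.frame.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped == len(dataset.frame):
        raise DegenerateDatasetError(
            f"{dataset.name}: every row contains a missing value"
        )
    out = dataset.copy()
    out.frame = out.frame[complete].reset_index(drop=True)
    out.class_labels = out.class_labels[complete.to_numpy()].reset_index(drop=True)
    if n_dropped:
        out.provenance.append(f"dropped {n_dropped} incomplete rows")
    return out


def preprocess(dataset: TabularDataset, *, threshold: float = 0.30) -> TabularDataset:
    """Sparse-attribute drop followed by complete-case row filtering.

    ``raw_missing_ratio`` is carried through unchanged from the loaded data.
    Idempotent: the output contains no missing cells, so a second application
    is the identity.
    """
    return drop_incomplete_rows(drop_sparse_attributes(dataset, threshold))


def dataset_category(dataset: TabularDataset) -> DatasetCategory:
    """Classify a dataset as continuous, discrete, or mixed by its kinds."""
    if not dataset.kinds:
        raise DegenerateDatasetError(f"{dataset.name}: no attributes")
    if all(k is VariableKind.CONTINUOUS for k in dataset.kinds):
        return DatasetCategory.CONTINUOUS
    if all(k.is_discrete for k in dataset.kinds):
        return DatasetCategory.DISCRETE
    return DatasetCategory.MIXED


def concat_same_schema(datasets: Iterable[TabularDataset]) -> TabularDataset:
    """Row-wise concatenation of datasets sharing column names and kinds."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to concatenate")
    first = datasets[0]
    for d in datasets[1:]:
        if list(d.frame.columns) != list(first.frame.columns) or d.kinds != first.kinds:
            raise SchemaError("datasets do not share a schema")
    out = first.copy()
    out.frame = pd.concat([d.frame for d in datasets], ignore_index=True)
    out.class_labels = pd.concat(
        [d.class_labels for d in datasets], ignore_index=True
    )
    total = sum(d.frame.size for d in datasets)
    missing = sum(d.raw_missing_ratio * d.frame.size for d in datasets)
    out.raw_missing_ratio = missing / total if total else 0.0
    return out
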