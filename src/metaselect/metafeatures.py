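"""The 26 dataset-characterization indicators plus the domain field label.

Three indicator families summarize a classification dataset:

* **simple** — counts and ratios: number of variables P, sample size N,
  number of classes N_class, largest/least class ratios, binary / discrete /
  continuous variable ratios, and the missing-value ratio of the data as
  loaded;
* **statistical** — location, spread and shape statistics of the continuous
  attributes (geometric/harmonic/trimmed means, a percentile, MAD, variance,
  standard deviation, interquartile range, index of dispersion, skewness,
  kurtosis), each averaged over the eligible continuous attributes, plus the
  mean absolute pairwise Pearson correlation MAr;
* **information-theoretic** — class entropy E_C, mean attribute entropy
  ME_V, mean attribute–class mutual information MME_CV, the equivalent
  number of variables ENV = E_C / MME_CV, and the noise–signal ratio
  NSR = (ME_V − MME_CV) / MME_CV.

Entropies are in bits by default.  Continuous attributes are discretized by
equal-width histogram before entropy/MI computation; the default bin count
follows Sturges' rule.  Indicators whose preconditions fail (no continuous
attribute, non-positive values under a geometric mean, zero MME_CV) are set
to a neutral value and recorded in ``flags`` rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DomainTag, TabularDataset, VariableKind

__all__ = [
    "MetafeatureVector",
    "METAFEATURE_NAMES",
    "shannon_entropy",
    "mutual_information",
    "discretize_equal_width",
    "sturges_bins",
    "simple_metafeatures",
    "statistical_metafeatures",
    "information_metafeatures",
    "characterize",
]

#: The 26 indicator names, in stable reporting order.
METAFEATURE_NAMES = (
    "P", "N", "N_class", "R_largest", "R_least",
    "R_binary", "R_discrete", "R_continuous", "R_missing",
    "Geomean", "Harmean", "Trimean", "Prctile", "MAD",
    "Var", "Std", "MAr", "IQR", "D", "Skewness", "Kurtosis",
    "ME_V", "E_C", "MME_CV", "ENV", "NSR",
)


@dataclass
class MetafeatureVector:
    """One dataset's 26 indicators plus its domain field label."""

    values: dict[str, float]
    field_label: DomainTag
    flags: dict[str, str] = field(default_factory=dict)

    def __getattr__(self, name: str) -> float:
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        s = pd.Series({k: self.values.get(k, np.nan) for k in METAFEATURE_NAMES})
        s["field_label"] = self.field_label.value
        return s

    def merged(self, other: "MetafeatureVector") -> "MetafeatureVector":
        return MetafeatureVector(
            values={**self.values, **other.values},
            field_label=self.field_label,
            flags={**self.flags, **other.flags},
        )


def shannon_entropy(counts: Sequence[int] | np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of a count vector: −Σ p_i log_base p_i.

    Zero counts contribute nothing; the result lies in [0, log_base k].
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("counts must sum to a positive total")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    p = counts[counts > 0] / counts.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def mutual_information(x: Sequence, y: Sequence, base: float = 2.0) -> float:
    """Mutual information I(X;Y) = H(X) + H(Y) − H(X,Y) from the joint table.

    Inputs are treated as discrete level vectors.  The result is clamped at
    zero against floating-point round-off.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) == 0:
        raise ValueError("empty input")
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    h_x = shannon_entropy(joint.sum(axis=1), base)
    h_y = shannon_entropy(joint.sum(axis=0), base)
    h_xy = shannon_entropy(joint.ravel(), base)
    return max(0.0, h_x + h_y - h_xy)


def discretize_equal_width(values: Sequence[float], n_bins: int) -> np.ndarray:
    """Equal-width binning over [min, max]; the maximum falls in the last bin.

    A constant vector occupies bin 0 only.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.zeros(values.shape, dtype=int)
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def sturges_bins(n: int) -> int:
    """Sturges' histogram-bin rule, floored at 2 bins."""
    return max(2, int(math.ceil(math.log2(max(n, 1)))) + 1)


def _continuous_columns(dataset: TabularDataset) -> list[str]:
    return [c for c, k in dataset.columns if k is VariableKind.CONTINUOUS]


def simple_metafeatures(dataset: TabularDataset) -> MetafeatureVector:
    """P, N, N_class, class-ratio and variable-kind-ratio indicators.

    R_missing reports the missing fraction of the dataset *as loaded*
    (``raw_missing_ratio``), since the preprocessed matrix is complete.
    """
    n, p = dataset.n_rows, dataset.n_attributes
    class_counts = dataset.class_labels.value_counts()
    kinds = dataset.kinds
    values = {
        "P": float(p),
        "N": float(n),
        "N_class": float(len(class_counts)),
        "R_largest": float(class_counts.max() / n),
        "R_least": float(class_counts.min() / n),
        "R_binary": sum(k is VariableKind.BINARY for k in kinds) / p,
        "R_discrete": sum(k.is_discrete for k in kinds) / p,
        "R_continuous": sum(k is VariableKind.CONTINUOUS for k in kinds) / p,
        "R_missing": float(dataset.raw_missing_ratio),
    }
    return MetafeatureVector(values=values, field_label=dataset.domain)


def statistical_metafeatures(
    dataset: TabularDataset,
    *,
    trim_fraction: float = 0.1,
    percentile: float = 90.0,
) -> MetafeatureVector:
    """Spread/shape statistics of continuous attributes, averaged across them.

    Per attribute: geometric mean, harmonic mean, trimmed mean (trimming
    ``trim_fraction`` from each tail), the ``percentile``-th percentile,
    mean absolute deviation about the mean, sample variance (n−1), standard
    deviation, interquartile range, index of dispersion (variance/mean),
    skewness (biased g1) and kurtosis (non-excess; normal → 3).  Each
    statistic is the arithmetic mean over the attributes for which it is
    defined; undefined cases (non-positive values for the geometric /
    harmonic mean, zero mean for the dispersion index) are excluded and
    flagged.  MAr is the mean |Pearson r| over all unordered pairs of
    continuous attributes (0 with fewer than two).
    """
    flags: dict[str, str] = {}
    cols = _continuous_columns(dataset)
    stat_names = ("Geomean", "Harmean", "Trimean", "Prctile", "MAD", "Var",
                  "Std", "MAr", "IQR", "D", "Skewness", "Kurtosis")
    if not cols:
        flags["statistical"] = "no continuous attributes; statistics set to 0"
        return MetafeatureVector(
            values={k: 0.0 for k in stat_names},
            field_label=dataset.domain,
            flags=flags,
        )

    per_attr: dict[str, list[float]] = {k: [] for k in stat_names if k != "MAr"}
    for col in cols:
        x = dataset.frame[col].to_numpy(dtype=float)
        if (x > 0).all():
            per_attr["Geomean"].append(float(stats.gmean(x)))
            per_attr["Harmean"].append(float(stats.hmean(x)))
        else:
            flags["Geomean"] = (flags.get("Geomean", "") + f" {col}").strip()
        per_attr["Trimean"].append(
            float(stats.trim_mean(x, proportiontocut=trim_fraction))
        )
        per_attr["Prctile"].append(float(np.percentile(x, percentile)))
        per_attr["MAD"].append(float(np.abs(x - x.mean()).mean()))
        var = float(np.var(x, ddof=1)) if len(x) > 1 else 0.0
        per_attr["Var"].append(var)
        per_attr["Std"].append(math.sqrt(var))
        q75, q25 = np.percentile(x, [75, 25])
        per_attr["IQR"].append(float(q75 - q25))
        if x.mean() != 0:
            per_attr["D"].append(var / float(x.mean()))
        else:
            flags["D"] = (flags.get("D", "") + f" {col}").strip()
        per_attr["Skewness"].append(float(stats.skew(x, bias=True)))
        per_attr["Kurtosis"].append(float(stats.kurtosis(x, fisher=False, bias=True)))

    if flags.get("Geomean"):
        flags["Geomean"] = (
            "non-positive values, excluded from Geomean/Harmean: " + flags["Geomean"]
        )
    if flags.get("D"):
        flags["D"] = "zero mean, excluded from dispersion index: " + flags["D"]

    values = {
        k: (float(np.mean(v)) if v else 0.0) for k, v in per_attr.items()
    }

    if len(cols) >= 2:
        corr = dataset.frame[cols].astype(float).corr().to_numpy()
        iu = np.triu_indices_from(corr, k=1)
        pair = np.abs(corr[iu])
        values["MAr"] = float(np.nanmean(pair)) if pair.size else 0.0
    else:
        values["MAr"] = 0.0

    return MetafeatureVector(values=values, field_label=dataset.domain, flags=flags)


def information_metafeatures(
    dataset: TabularDataset,
    n_bins: int | None = None,
    base: float = 2.0,
) -> MetafeatureVector:
    """Entropy-based indicators.

    E_C is the class entropy.  Each attribute (continuous ones discretized
    into ``n_bins`` equal-width bins; default Sturges) yields an entropy and
    a mutual information with the class; ME_V and MME_CV are their means.
    ENV = E_C / MME_CV and NSR = (ME_V − MME_CV) / MME_CV; when MME_CV is
    zero both are flagged and stored as +inf.
    """
    flags: dict[str, str] = {}
    bins = n_bins if n_bins is not None else sturges_bins(dataset.n_rows)
    y = dataset.class_labels.to_numpy()
    e_c = shannon_entropy(dataset.class_labels.value_counts().to_numpy(), base)

    attr_entropies: list[float] = []
    attr_mis: list[float] = []
    for col, kind in dataset.columns:
        raw = dataset.frame[col]
        if kind is VariableKind.CONTINUOUS:
            levels = discretize_equal_width(raw.to_numpy(dtype=float), bins)
        else:
            levels = raw.to_numpy()
        counts = pd.Series(levels).value_counts().to_numpy()
        attr_entropies.append(shannon_entropy(counts, base))
        attr_mis.append(mutual_information(levels, y, base))

    me_v = float(np.mean(attr_entropies)) if attr_entropies else 0.0
    mme_cv = float(np.mean(attr_mis)) if attr_mis else 0.0
    if mme_cv > 0:
        env = e_c / mme_cv
        nsr = (me_v - mme_cv) / mme_cv
    else:
        env = math.inf
        nsr = math.inf
        flags["ENV"] = flags["NSR"] = "MME_CV is zero; ratio undefined (+inf)"

    return MetafeatureVector(
        values={"ME_V": me_v, "E_C": e_c, "MME_CV": mme_cv, "ENV": env, "NSR": nsr},
        field_label=dataset.domain,
        flags=flags,
    )


def characterize(
    dataset: TabularDataset,
    *,
    n_bins: int | None = None,
    base: float = 2.0,
    trim_fraction: float = 0.1,
    percentile: float = 90.0,
) -> MetafeatureVector:
    """All 26 indicators plus the field label, as one vector."""
    mf = simple_metafeatures(dataset)
    mf = mf.merged(
        statistical_metafeatures(
            dataset, trim_fraction=trim_fraction, percentile=percentile
        )
    )
    mf = mf.merged(information_metafeatures(dataset, n_bins=n_bins, base=base))
    return mf
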