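"""Benchmark the eight base classifiers on a dataset.

Eight mature algorithm families act as the candidate pool: logistic
regression (LR), the C4.5-style decision tree (C45), support vector machine
(SVM), AdaBoost (AB), k-nearest neighbours (kNN), naive Bayes (NB), random
forest (RF) and a single-hidden-layer backpropagation network (BP).  Each
(algorithm, dataset) run yields a :class:`PerformanceRecord` carrying train
and test accuracy, the recall of the most and least frequent classes
(S_largest / S_least, the multiclass analogues of sensitivity and
specificity), the log10 of the fit wall-clock time and the log10 of the
fitted model's serialized size in bytes.  Time and memory span orders of
magnitude across datasets, hence the log10 scale.

Runs that violate resource limits are captured, never raised, under a fixed
failure taxonomy: dimension_limit (too many dummy coefficients after one-hot
expansion, LR/BP), category_limit (a discrete attribute with too many
levels, RF), memory_limit, timeout, numeric_error.
"""

from __future__ import annotations

import enum
import math
import pickle
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import TabularDataset, VariableKind

__all__ = [
    "AlgorithmId",
    "ALGORITHM_ORDER",
    "ResourceLimits",
    "PerformanceRecord",
    "FailureReason",
    "s_largest",
    "s_least",
    "evaluate_algorithm",
    "benchmark_suite",
    "records_to_frame",
]


class AlgorithmId(enum.Enum):
    LR = "LR"
    C45 = "C4.5"
    SVM = "SVM"
    AB = "AB"
    KNN = "kNN"
    NB = "NB"
    RF = "RF"
    BP = "BP"


#: Fixed algorithm order used for reporting and tie-breaking.
ALGORITHM_ORDER = (
    AlgorithmId.LR, AlgorithmId.C45, AlgorithmId.SVM, AlgorithmId.AB,
    AlgorithmId.KNN, AlgorithmId.NB, AlgorithmId.RF, AlgorithmId.BP,
)


class FailureReason(enum.Enum):
    NONE = "none"
    DIMENSION_LIMIT = "dimension_limit"
    CATEGORY_LIMIT = "category_limit"
    MEMORY_LIMIT = "memory_limit"
    TIMEOUT = "timeout"
    NUMERIC_ERROR = "numeric_error"


@dataclass
class ResourceLimits:
    """Caps a benchmark run enforces.

    The original thresholds these emulate (a solver's maximum coefficient
    count, a system memory allocation) are platform-specific; defaults here
    are generous and configurable.
    """

    timeout_seconds: float = 300.0
    memory_cap_bytes: int = 2 * 1024**3
    max_dummy_coefficients: int = 10_000
    max_category_levels: int = 512

    def __post_init__(self) -> None:
        if min(self.timeout_seconds, self.memory_cap_bytes,
               self.max_dummy_coefficients, self.max_category_levels) <= 0:
            raise ValueError("all resource limits must be positive")


@dataclass
class PerformanceRecord:
    """Outcome of one algorithm on one dataset."""

    algorithm: AlgorithmId
    dataset_name: str
    status: str  # "completed" | "failed"
    failure_reason: FailureReason = FailureReason.NONE
    acc_train: float | None = None
    acc_test: float | None = None
    s_largest: float | None = None
    s_least: float | None = None
    fit_seconds: float | None = None
    model_bytes: int | None = None
    log10_time: float | None = None
    log10_memory: float | None = None
    seed: int = 0
    detail: str = ""

    @property
    def completed(self) -> bool:
        return self.status == "completed"


def s_largest(y_true, y_pred) -> float:
    """Recall of the most frequent true class, as a percentage.

    Ties on the most frequent class are broken by label sort order.
    """
    return _class_recall(y_true, y_pred, largest=True)


def s_least(y_true, y_pred) -> float:
    """Recall of the least frequent true class, as a percentage."""
    return _class_recall(y_true, y_pred, largest=False)


def _class_recall(y_true, y_pred, *, largest: bool) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    labels, counts = np.unique(y_true, return_counts=True)
    # np.unique sorts labels, so argmax/argmin break ties by sort order
    idx = int(np.argmax(counts)) if largest else int(np.argmin(counts))
    target = labels[idx]
    mask = y_true == target
    return float(100.0 * (y_pred[mask] == target).mean())


def _default_learners(seed: int) -> dict[AlgorithmId, object]:
    """Fixed-hyperparameter base learners (documented in the methods note)."""
    return {
        AlgorithmId.LR: LogisticRegression(max_iter=2000, random_state=seed),
        AlgorithmId.C45: DecisionTreeClassifier(
            criterion="entropy", random_state=seed
        ),
        AlgorithmId.SVM: SVC(kernel="rbf", random_state=seed),
        AlgorithmId.AB: AdaBoostClassifier(n_estimators=50, random_state=seed),
        AlgorithmId.KNN: KNeighborsClassifier(n_neighbors=5),
        AlgorithmId.NB: GaussianNB(),
        AlgorithmId.RF: RandomForestClassifier(n_estimators=100, random_state=seed),
        AlgorithmId.BP: MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=500, random_state=seed
        ),
    }

#: Algorithms that get standardized numeric inputs (distance/gradient based).
_SCALED = {AlgorithmId.LR, AlgorithmId.SVM, AlgorithmId.KNN, AlgorithmId.BP}


def _design_info(dataset: TabularDataset) -> tuple[list[str], list[str], int, int]:
    """Discrete/continuous column split, dummy-column count, max level count."""
    discrete = [c for c, k in dataset.columns if k.is_discrete]
    continuous = [c for c, k in dataset.columns if k is VariableKind.CONTINUOUS]
    levels = [dataset.frame[c].nunique() for c in discrete]
    n_dummy = sum(levels) + len(continuous)
    return discrete, continuous, n_dummy, (max(levels) if levels else 0)


def _make_pipeline(algorithm: AlgorithmId, dataset: TabularDataset, seed: int,
                   learners: dict | None = None) -> Pipeline:
    discrete, continuous, _, _ = _design_info(dataset)
    transformers = []
    if discrete:
        transformers.append(
            ("onehot", OneHotEncoder(handle_unknown="ignore", sparse_output=False),
             discrete)
        )
    if continuous:
        scale = StandardScaler() if algorithm in _SCALED else "passthrough"
        transformers.append(("num", scale, continuous))
    learner = (learners or _default_learners(seed))[algorithm]
    return Pipeline(
        [("prep", ColumnTransformer(transformers)), ("model", learner)]
    )


def evaluate_algorithm(
    dataset: TabularDataset,
    algorithm: AlgorithmId,
    *,
    test_size: float = 0.30,
    limits: ResourceLimits | None = None,
    seed: int = 0,
    learners: dict | None = None,
) -> PerformanceRecord:
    """Fit one algorithm on a stratified holdout split and record performance.

    Pre-checks enforce structural limits before any fitting: the one-hot
    dummy-coefficient count for LR and BP (dimension_limit) and the maximum
    discrete level count for RF (category_limit).  The fit is timed with the
    wall clock; the fitted model is measured as its pickle size in bytes.
    All failures are returned as failed records, never raised.
    """
    limits = limits or ResourceLimits()
    rec = PerformanceRecord(algorithm=algorithm, dataset_name=dataset.name,
                            status="failed", seed=seed)

    discrete, _, n_dummy, max_levels = _design_info(dataset)
    if algorithm in (AlgorithmId.LR, AlgorithmId.BP) and \
            n_dummy > limits.max_dummy_coefficients:
        rec.failure_reason = FailureReason.DIMENSION_LIMIT
        rec.detail = f"{n_dummy} dummy coefficients > {limits.max_dummy_coefficients}"
        return rec
    if algorithm is AlgorithmId.RF and max_levels > limits.max_category_levels:
        rec.failure_reason = FailureReason.CATEGORY_LIMIT
        rec.detail = f"{max_levels} levels > {limits.max_category_levels}"
        return rec

    X = dataset.frame
    y = dataset.class_labels.to_numpy()
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=seed
        )
        pipe = _make_pipeline(algorithm, dataset, seed, learners)
        t0 = time.perf_counter()
        pipe.fit(X_tr, y_tr)
        elapsed = time.perf_counter() - t0
        if elapsed > limits.timeout_seconds:
            rec.failure_reason = FailureReason.TIMEOUT
            rec.detail = f"fit took {elapsed:.3g}s > {limits.timeout_seconds}s"
            return rec
        model_bytes = len(pickle.dumps(pipe.named_steps["model"]))
        if model_bytes > limits.memory_cap_bytes:
            rec.failure_reason = FailureReason.MEMORY_LIMIT
            rec.detail = f"model {model_bytes}B > {limits.memory_cap_bytes}B"
            return rec
        pred_tr = pipe.predict(X_tr)
        pred_te = pipe.predict(X_te)
    except (ValueError, FloatingPointError, np.linalg.LinAlgError,
            MemoryError) as exc:
        rec.failure_reason = FailureReason.NUMERIC_ERROR
        rec.detail = str(exc)
        return rec

    rec.status = "completed"
    rec.failure_reason = FailureReason.NONE
    rec.acc_train = float((pred_tr == y_tr).mean())
    rec.acc_test = float((pred_te == y_te).mean())
    rec.s_largest = s_largest(y_te, pred_te)
    rec.s_least = s_least(y_te, pred_te)
    rec.fit_seconds = elapsed
    rec.model_bytes = model_bytes
    rec.log10_time = math.log10(max(elapsed, 1e-9))
    rec.log10_memory = math.log10(model_bytes)
    return rec


def benchmark_suite(
    datasets,
    algorithms=ALGORITHM_ORDER,
    *,
    limits: ResourceLimits | None = None,
    seed: int = 0,
    test_size: float = 0.30,
) -> list[PerformanceRecord]:
    """One record per (dataset, algorithm), in deterministic order."""
    records = []
    for ds in datasets:
        for alg in algorithms:
            records.append(
                evaluate_algorithm(
                    ds, alg, limits=limits, seed=seed, test_size=test_size
                )
            )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Flatten performance records to a DataFrame (the CSV contract)."""
    rows = []
    for r in records:
        rows.append({
            "dataset": r.dataset_name,
            "algorithm": r.algorithm.value,
            "status": r.status,
            "failure_reason": r.failure_reason.value,
            "acc_train": r.acc_train,
            "acc_test": r.acc_test,
            "s_largest": r.s_largest,
            "s_least": r.s_least,
            "fit_seconds": r.fit_seconds,
            "model_bytes": r.model_bytes,
            "log10_time": r.log10_time,
            "log10_memory": r.log10_memory,
            "seed": r.seed,
        })
    return pd.DataFrame(rows)
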