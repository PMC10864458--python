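"""Discretize per-dataset algorithm rankings into recommendation labels.

Per dataset, the eight algorithms are ranked by test accuracy; the top three
are labeled recommended (Y), ranks four and five medium (M), and ranks six
through eight — along with any algorithm whose modeling failed — not
recommended (No).  Ranking on a discretized label rather than the raw
accuracy keeps the downstream meta-learning robust to small accuracy
differences.

Ties are broken by S_least (higher first), then fit time (lower first), then
the fixed algorithm order; the tie-break chain is a package convention.
"""

from __future__ import annotations

import enum

import pandas as pd

from .benchmark import ALGORITHM_ORDER, AlgorithmId, PerformanceRecord

__all__ = ["ApplicabilityLabel", "rank_algorithms", "assign_labels",
           "label_matrix", "to_binary"]


class ApplicabilityLabel(enum.Enum):
    Y = "Y"
    M = "M"
    NO = "No"


def rank_algorithms(records: list[PerformanceRecord]) -> list[PerformanceRecord]:
    """Order one dataset's records: completed first by accuracy, failed last.

    Completed records sort by test accuracy descending, ties by S_least
    descending, then log10 time ascending, then fixed algorithm order.
    Failed records keep the fixed algorithm order among themselves.
    """
    names = {r.dataset_name for r in records}
    if len(names) > 1:
        raise ValueError(f"records span multiple datasets: {sorted(names)}")
    completed = [r for r in records if r.completed]
    failed = [r for r in records if not r.completed]
    if not completed:
        raise ValueError("no completed records to rank")
    order = {a: i for i, a in enumerate(ALGORITHM_ORDER)}
    completed.sort(
        key=lambda r: (-r.acc_test, -r.s_least, r.log10_time, order[r.algorithm])
    )
    failed.sort(key=lambda r: order[r.algorithm])
    return completed + failed


def assign_labels(
    ranking: list[PerformanceRecord],
) -> dict[AlgorithmId, ApplicabilityLabel]:
    """Map ranks to labels: 1–3 → Y, 4–5 → M, 6–8 and failures → No."""
    labels: dict[AlgorithmId, ApplicabilityLabel] = {}
    rank = 0
    for rec in ranking:
        if not rec.completed:
            labels[rec.algorithm] = ApplicabilityLabel.NO
            continue
        rank += 1
        if rank <= 3:
            labels[rec.algorithm] = ApplicabilityLabel.Y
        elif rank <= 5:
            labels[rec.algorithm] = ApplicabilityLabel.M
        else:
            labels[rec.algorithm] = ApplicabilityLabel.NO
    return labels


def to_binary(label: ApplicabilityLabel) -> int:
    """Binary recommend-or-not view: Y → 1, {M, No} → 0."""
    return 1 if label is ApplicabilityLabel.Y else 0


def label_matrix(records: list[PerformanceRecord]) -> pd.DataFrame:
    """Dataset × algorithm label matrix from a benchmark record collection."""
    by_dataset: dict[str, list[PerformanceRecord]] = {}
    for r in records:
        by_dataset.setdefault(r.dataset_name, []).append(r)
    rows = {}
    for name, recs in sorted(by_dataset.items()):
        labels = assign_labels(rank_algorithms(recs))
        rows[name] = {a.value: labels[a].value for a in ALGORITHM_ORDER if a in labels}
    return pd.DataFrame.from_dict(rows, orient="index")[
        [a.value for a in ALGORITHM_ORDER]
    ]
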