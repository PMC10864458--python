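import numpy as np
import pandas as pd
import pytest

from metaselect import (
    BaseDatasetSpec,
    DomainTag,
    TabularDataset,
    VariableKind,
    generate_base_dataset,
)


@pytest.fixture
def tiny_dataset() -> TabularDataset:
    """Hand-built 10-row mixed dataset with known values."""
    frame = pd.DataFrame({
        "age": [1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5, 2.0, 3.0],
        "flag": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
        "grade": ["a", "b", "a", "c", "a", "b", "c", "a", "b", "a"],
    })
    return TabularDataset(
        name="tiny",
        frame=frame,
        kinds=[VariableKind.CONTINUOUS, VariableKind.BINARY,
               VariableKind.DISCRETE],
        class_labels=pd.Series(["x", "y"] * 5),
        domain=DomainTag.MEDICAL,
    )


@pytest.fixture
def separable_dataset() -> TabularDataset:
    """Two well-separated Gaussian classes; every learner should ace it."""
    spec = BaseDatasetSpec(
        n_rows=240, n_continuous=3, n_discrete=1, n_binary=1, n_classes=2,
        class_separation=5.0, attribute_class_dependence=0.9,
        name="separable",
    )
    return generate_base_dataset(spec, seed=11)


@pytest.fixture
def missing_dataset() -> TabularDataset:
    """Dataset with one very sparse column and a few incomplete rows."""
    rng = np.random.default_rng(0)
    n = 20
    frame = pd.DataFrame({
        "dense": rng.normal(size=n),
        "sparse": [np.nan] * 8 + list(rng.normal(size=n - 8)),  # 40% missing
        "spotty": [np.nan, np.nan] + list(rng.normal(size=n - 2)),  # 10%
    })
    return TabularDataset(
        name="holey",
        frame=frame,
        kinds=[VariableKind.CONTINUOUS] * 3,
        class_labels=pd.Series(["u", "v"] * (n // 2)),
        domain=DomainTag.GENERAL,
        raw_missing_ratio=float(frame.isna().to_numpy().mean()),
    )
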