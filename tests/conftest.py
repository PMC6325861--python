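import numpy as np
import pytest

from hpscore import DatasetSpec, LabeledDataset, generate_labeled_dataset


@pytest.fixture(scope="session")
def default_dataset() -> LabeledDataset:
    """The 106/194 replication-profile dataset, seed 0."""
    return generate_labeled_dataset(DatasetSpec(seed=0))


@pytest.fixture(scope="session")
def separated_dataset() -> LabeledDataset:
    """Degenerate fully separated profile: positives all-ones, negatives all-zeros."""
    spec = DatasetSpec(
        p_positive=(1.0,) * 9,
        p_negative=(0.0,) * 9,
        correlated_pairs=(),
        seed=0,
    )
    return generate_labeled_dataset(spec)


def make_dataset(X, y=None, ids=None) -> LabeledDataset:
    X = np.asarray(X, dtype=np.int8)
    if ids is None:
        ids = [f"P{i:03d}" for i in range(X.shape[0])]
    return LabeledDataset(ids=ids, X=X, y=None if y is None else np.asarray(y))
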