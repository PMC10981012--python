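import numpy as np
import pandas as pd
import pytest

from mirtransfer.records import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def toy_table(n=400, n_features=5, seed=0, species="toy", weights=None,
              groups=None):
    """Small linearly-separated feature table for model tests."""
    r = np.random.default_rng(seed)
    X = r.normal(0, 1, (n, n_features))
    w = np.zeros(n_features)
    w[:2] = [3.0, -3.0] if weights is None else weights[:2]
    y = (X @ w + r.normal(0, 0.1, n) > 0).astype(int)
    if groups is None:
        groups = [f"{species}-mir-{i % 25}" for i in range(n)]
    return FeatureTable.from_arrays(
        X, y, [f"f{i}" for i in range(n_features)],
        ids=[f"{species}-{i}" for i in range(n)],
        mirna_ids=groups, species=species)


@pytest.fixture
def separable_table():
    return toy_table()


@pytest.fixture
def separable_validation():
    return toy_table(n=100, seed=1)
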