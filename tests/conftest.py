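import numpy as np
import pytest

from pseudoneg import LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    """4 positives, 8 negatives, 6 features; positives share a profile."""
    profile = rng.normal(0, 2, 6)
    X = np.vstack([
        rng.normal(profile, 1.0, (4, 6)),
        rng.normal(0, 1.0, (8, 6)),
    ])
    labels = np.array([True] * 4 + [False] * 8)
    return LabeledDataset(features=X, labels=labels)


def random_dataset(rng, m, n, f):
    """Unstructured random dataset: m positives then n negatives."""
    X = rng.normal(size=(m + n, f))
    labels = np.array([True] * m + [False] * n)
    return LabeledDataset(features=X, labels=labels)


def rows_with_correlations(C, f=8, seed=0):
    """Rows whose sample pairwise Pearson correlations equal C exactly.

    Builds an orthonormal zero-mean basis B and returns L @ B where
    C = L L^T; each returned row then has zero mean, unit sum of squares,
    and row-correlation matrix exactly C (up to float rounding).
    """
    k = C.shape[0]
    assert f >= k + 1
    g = np.random.default_rng(seed)
    B = g.normal(size=(k, f))
    B -= B.mean(axis=1, keepdims=True)
    # Gram-Schmidt; linear combinations of zero-mean rows stay zero-mean
    for i in range(k):
        for j in range(i):
            B[i] -= (B[i] @ B[j]) * B[j]
        B[i] /= np.linalg.norm(B[i])
    L = np.linalg.cholesky(C)
    return L @ B
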