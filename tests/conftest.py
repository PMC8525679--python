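import numpy as np
import pytest

from metprio import (
    AssociationSet,
    DescriptorMatrix,
    FixtureSpec,
    SimilarityNetwork,
    generate_fixture,
)


@pytest.fixture(scope="session")
def default_fixture():
    """Well-separated 4-cluster study: the standard end-to-end input."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """Fast fixture for CLI / pipeline smoke tests."""
    return FixtureSpec(n_metabolites=60, n_descriptors=30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_network(rng):
    """Random symmetric positive-weight 5-node similarity network."""
    n = 5
    raw = rng.uniform(0.1, 1.0, size=(n, n))
    adj = (raw + raw.T) / 2
    np.fill_diagonal(adj, 1.0)
    return SimilarityNetwork([f"n{i}" for i in range(n)], adj)


@pytest.fixture
def toy_associations():
    """Ten metabolites: m0-m4 focal positives (m4 also tied to another
    disease), m5-m7 other-disease only, m8-m9 unassigned."""
    pairs = {
        ("OC", "m0"), ("OC", "m1"), ("OC", "m2"), ("OC", "m3"), ("OC", "m4"),
        ("D1", "m4"), ("D1", "m5"), ("D1", "m6"), ("D2", "m7"),
    }
    return AssociationSet(pairs, "OC", no_disease_metabolites={"m8", "m9"})


def brute_force_auc(y, scores):
    """AUC as the fraction of concordant positive-negative score pairs,
    counting ties as half."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
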