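import numpy as np
import pytest

import tskfuzzy as tf
from tskfuzzy import subspace as sub


def random_instance(seed, n_clusters=2, n_features=3, n_samples=5):
    """A random data/state pair satisfying the clustering-state invariants."""
    rng = np.random.default_rng(seed)
    data = tf.FeatureMatrix(rng.normal(size=(n_samples, n_features)))
    u = rng.dirichlet(np.ones(n_clusters), size=n_samples).T
    state = sub.ClusteringState(
        memberships=u,
        centers=rng.normal(size=(n_clusters, n_features)),
        weights=rng.dirichlet(np.ones(n_features), size=n_clusters),
        regularizers=rng.uniform(0.5, 2.0, size=n_clusters),
    )
    config = tf.ClusteringConfig(n_clusters=n_clusters, seed=seed)
    return data, state, config


@pytest.fixture
def subspace_data():
    """Well-separated 3-cluster table with known informative features."""
    spec = tf.SyntheticSpec(seed=0)
    return tf.generate_subspace_clusters(spec)


@pytest.fixture
def small_tsk_model():
    """A coherent 3-rule, 4-feature ground-truth model pair."""
    rng = np.random.default_rng(3)
    k, d = 3, 4
    antecedent = tf.AntecedentModel(
        centers=rng.normal(size=(k, d)) * 2.0,
        spreads=np.full((k, d), 0.5),
        active=np.ones((k, d), dtype=bool),
        threshold=0.0,
        spread_scale=0.5,
    )
    consequent = tf.ConsequentModel(
        [rng.normal(size=d + 1) for _ in range(k)], mode="reduced", ridge=0.0
    )
    return antecedent, consequent


@pytest.fixture
def adni_like():
    return tf.generate_adni_like_table(seed=0)


def match_clusters(hard_assignments, truth_assignments, n_clusters):
    """Map each fitted cluster to the ground-truth cluster it overlaps most."""
    mapping = {}
    for c in range(n_clusters):
        overlaps = [
            np.sum((hard_assignments == c) & (truth_assignments == t))
            for t in range(n_clusters)
        ]
        mapping[c] = int(np.argmax(overlaps))
    return mapping
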