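"""Synthetic data generators for every stage of the pipeline.

Three generators cover the testing needs: subspace-structured clusters
(each cluster compact on only a few informative features, broad elsewhere),
feature tables labeled by a known ground-truth TSK model (so consequent
recovery is checkable against the generating coefficients), and a small
positive-valued two-class table with latent cluster structure shaped like a
region-mean brain-imaging feature table.  Every generator is a pure function
of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .antecedent import AntecedentModel
from .model import ConsequentModel, TSKClassifier, predict_scores
from .subspace import FeatureMatrix, ValidationError


@dataclass
class SyntheticSpec:
    """Parameters of the subspace-cluster generator.

    ``informative_variance`` must be well below ``noise_variance`` for
    feature-weight recovery to be well-posed: informative features are the
    ones on which a cluster is tight, and the clustering should award them
    the larger weights.
    """

    n_samples: int = 300
    n_features: int = 10
    n_clusters: int = 3
    informative_features_per_cluster: int = 3
    informative_variance: float = 0.01
    noise_variance: float = 1.0
    center_separation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_samples,
            self.n_features,
            self.n_clusters,
            self.informative_features_per_cluster,
        ) < 1:
            raise ValidationError("all counts must be positive")
        if self.informative_features_per_cluster > self.n_features:
            raise ValidationError("more informative features than features")


def generate_subspace_clusters(
    spec: SyntheticSpec,
) -> tuple[FeatureMatrix, dict]:
    """Clusters that are tight on disjoint-ish informative feature subsets.

    For each cluster a random subset of features is informative: samples are
    drawn around a cluster-specific offset (spaced ``center_separation``
    apart) with small variance.  All other features are broad shared noise
    centered at zero.  Returns the table plus ground truth (assignments,
    generating centers, informative masks).
    """
    rng = np.random.default_rng(spec.seed)
    n, d, c = spec.n_samples, spec.n_features, spec.n_clusters
    masks = np.zeros((c, d), dtype=bool)
    for k in range(c):
        masks[k, rng.choice(d, size=spec.informative_features_per_cluster, replace=False)] = True
    # cluster offsets spread along each informative feature
    centers = np.zeros((c, d))
    for k in range(c):
        centers[k, masks[k]] = (k - (c - 1) / 2.0) * spec.center_separation
    assignments = rng.integers(0, c, size=n)
    values = rng.normal(0.0, np.sqrt(spec.noise_variance), size=(n, d))
    for k in range(c):
        rows = assignments == k
        m = masks[k]
        values[np.ix_(rows, m)] = rng.normal(
            centers[k, m],
            np.sqrt(spec.informative_variance),
            size=(int(rows.sum()), int(m.sum())),
        )
    data = FeatureMatrix(values=values)
    truth = {"assignments": assignments, "centers": centers, "informative": masks}
    return data, truth


def generate_tsk_labeled_data(
    antecedent: AntecedentModel,
    consequent: ConsequentModel,
    n: int = 400,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Feature table whose labels come from a known TSK model.

    Samples are drawn around the rule centers (one rule chosen uniformly per
    sample, Gaussian scatter with the rule's own spreads); the clean score is
    the model output, Gaussian noise of sd ``noise_sd`` is added, and the
    label is the sign (−1/+1, zero mapped to +1).  Returns the labeled table
    and the clean scores, so callers can filter on margin.
    """
    if n < 1:
        raise ValidationError("n must be positive")
    if len(consequent.coefficients) != antecedent.n_rules:
        raise ValidationError("incoherent antecedent/consequent pair")
    rng = np.random.default_rng(seed)
    k = antecedent.n_rules
    d = antecedent.n_features
    rules = rng.integers(0, k, size=n)
    sd = np.sqrt(antecedent.spreads)
    values = antecedent.centers[rules] + rng.normal(size=(n, d)) * sd[rules]
    scorer = TSKClassifier(
        antecedent=antecedent,
        consequent=consequent,
        label_map={-1: -1.0, 1: 1.0},
    )
    clean = predict_scores(values, scorer)
    noisy = clean + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    labels = np.where(noisy >= 0, 1, -1)
    data = FeatureMatrix(values=values, labels=labels)
    return data, clean


def generate_adni_like_table(seed: int = 0) -> FeatureMatrix:
    """A 200×15 positive-valued two-class table with 15 latent clusters.

    Mimics the shape of a region-mean intensity table after feature
    selection: 15 continuous positive features, two diagnostic classes, and
    latent cluster structure of unequal sizes in which each cluster is tight
    on a few features.  Intended for end-to-end and CLI tests, not as a
    model of real effect sizes.
    """
    rng = np.random.default_rng(seed)
    n, d, c = 200, 15, 15
    # unequal cluster sizes via a Dirichlet draw, at least 4 samples each
    sizes = np.maximum(rng.multinomial(n - 4 * c, rng.dirichlet(np.ones(c) * 2.0)) + 4, 4)
    while sizes.sum() != n:
        sizes[rng.integers(0, c)] += int(np.sign(n - sizes.sum()))
    base = 5.0 + rng.uniform(0.0, 2.0, size=d)  # intensity-like baselines
    values = np.empty((n, d))
    labels = np.empty(n, dtype=object)
    row = 0
    for k in range(c):
        m = np.zeros(d, dtype=bool)
        m[rng.choice(d, size=3, replace=False)] = True
        offset = np.zeros(d)
        offset[m] = rng.uniform(1.0, 3.0, size=3) * rng.choice([-1.0, 1.0], size=3)
        block = base + offset + rng.normal(size=(int(sizes[k]), d)) * np.where(m, 0.1, 0.6)
        values[row : row + sizes[k]] = block
        labels[row : row + sizes[k]] = "AD" if k % 2 == 0 else "HC"
        row += int(sizes[k])
    values = np.clip(values, 0.05, None)  # keep intensity-likeness
    perm = rng.permutation(n)
    return FeatureMatrix(values=values[perm], labels=labels[perm])
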