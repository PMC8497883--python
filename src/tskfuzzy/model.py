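"""The TSK fuzzy classifier: design vectors, consequent fit, prediction.

Each rule k contributes a linear consequent f^k(x); the system output is the
normalized-firing-strength-weighted sum over rules.  Writing the per-rule
blocks x̃^k = μ̃^k(x)·(1, x_k) and concatenating them turns the consequent
fit into ordinary (ridge) least squares on a fixed design matrix — the whole
consequent stage is one linear solve.

Two consequent layouts are supported: *reduced* restricts each rule's linear
function to the rule's active features (block length d_k + 1), *full* keeps
all d features in every consequent (block length d + 1) regardless of the
antecedent mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .antecedent import (
    AntecedentModel,
    activate_features,
    compute_antecedent_parameters,
    normalized_firing_matrix,
)
from .subspace import (
    ClusteringConfig,
    FeatureMatrix,
    ValidationError,
    fit_subspace_clustering,
)

logger = logging.getLogger(__name__)

MODES = ("reduced", "full")


@dataclass
class ConsequentModel:
    """Concatenated per-rule consequent coefficient vectors."""

    coefficients: list[np.ndarray]  # one (d_k + 1,) or (d + 1,) vector per rule
    mode: str = "reduced"
    ridge: float = 1e-4

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")
        if self.ridge < 0:
            raise ValidationError("ridge must be non-negative")
        self.coefficients = [np.asarray(p, dtype=float) for p in self.coefficients]
        if any(not np.all(np.isfinite(p)) for p in self.coefficients):
            raise ValidationError("non-finite consequent coefficients")

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "lambda": self.ridge,
            "coefficients": [p.tolist() for p in self.coefficients],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ConsequentModel":
        return cls(
            coefficients=[np.asarray(p, dtype=float) for p in payload["coefficients"]],
            mode=payload["mode"],
            ridge=float(payload["lambda"]),
        )


@dataclass
class TSKClassifier:
    """A fitted antecedent/consequent pair with its binary label encoding.

    ``label_map`` maps the two class labels to −1 and +1; the decision rule
    is score ≥ 0 → positive class (ties at exactly zero go positive).
    """

    antecedent: AntecedentModel
    consequent: ConsequentModel
    label_map: dict  # label -> -1.0 or +1.0
    feature_names: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.consequent.coefficients) != self.antecedent.n_rules:
            raise ValidationError("antecedent/consequent rule counts differ")
        if sorted(self.label_map.values()) != [-1.0, 1.0]:
            raise ValidationError("label_map must encode two labels as -1/+1")
        if not self.feature_names:
            self.feature_names = [f"x{j + 1}" for j in range(self.antecedent.n_features)]

    @property
    def positive_label(self):
        return next(k for k, v in self.label_map.items() if v == 1.0)

    @property
    def negative_label(self):
        return next(k for k, v in self.label_map.items() if v == -1.0)


# ---------------------------------------------------------------------------
# Design vectors
# ---------------------------------------------------------------------------


def design_block_slices(antecedent: AntecedentModel, mode: str) -> list[slice]:
    """Start/stop slices of each rule's block in the concatenated design."""
    if mode == "reduced":
        lengths = [int(dk) + 1 for dk in antecedent.active_counts]
    else:
        lengths = [antecedent.n_features + 1] * antecedent.n_rules
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]


def build_design_matrix(
    x: np.ndarray, antecedent: AntecedentModel, mode: str = "reduced"
) -> np.ndarray:
    """Design matrix for a batch of inputs, shape (N, Σ_k block_k)."""
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    strengths = normalized_firing_matrix(x, antecedent)  # (N, K)
    slices = design_block_slices(antecedent, mode)
    out = np.zeros((x.shape[0], slices[-1].stop))
    for k, sl in enumerate(slices):
        xe = x[:, antecedent.active[k]] if mode == "reduced" else x
        block = np.hstack([np.ones((x.shape[0], 1)), xe])
        out[:, sl] = strengths[:, [k]] * block
    return out


def build_design_vector(
    x: np.ndarray, antecedent: AntecedentModel, mode: str = "reduced"
) -> np.ndarray:
    """Concatenated per-rule design vector for a single input."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a single input vector")
    return build_design_matrix(x[None, :], antecedent, mode)[0]


# ---------------------------------------------------------------------------
# Consequent learning and prediction
# ---------------------------------------------------------------------------


def encode_labels(labels: np.ndarray, positive=None) -> tuple[np.ndarray, dict]:
    """Encode two class labels as ±1; positive defaults to the larger label."""
    classes = sorted(set(np.asarray(labels).tolist()))
    if len(classes) != 2:
        raise ValidationError("degenerate labels: need exactly two classes")
    if positive is None:
        positive = classes[1]
    if positive not in classes:
        raise ValidationError(f"positive label {positive!r} not present")
    negative = classes[0] if positive == classes[1] else classes[1]
    label_map = {negative: -1.0, positive: 1.0}
    y = np.array([label_map[l] for l in np.asarray(labels).tolist()])
    return y, label_map


def fit_consequents(
    data: FeatureMatrix,
    antecedent: AntecedentModel,
    ridge: float = 1e-4,
    mode: str = "reduced",
    positive=None,
    targets: np.ndarray | None = None,
) -> tuple[ConsequentModel, dict]:
    """Ridge least-squares fit of the concatenated consequent vector.

    Solves min_p Σ_n (y_n − pᵀ x_g(x_n))² + λ‖p‖² on the ±1-encoded labels
    via a single LAPACK least-squares solve of the ridge-augmented system
    (λ = 0 gives the minimum-norm plain solution).  Requires two classes
    with at least two samples each.

    ``targets`` replaces the encoded labels with arbitrary real regression
    targets (e.g. the clean scores of a generating model for round-trip
    checks); the label encoding then defaults to ±1.
    """
    if targets is not None:
        y = np.asarray(targets, dtype=float)
        if y.shape != (data.n_samples,):
            raise ValidationError("targets length mismatch")
        label_map = {-1: -1.0, 1: 1.0}
    else:
        if data.labels is None:
            raise ValidationError("training data carries no labels")
        y, label_map = encode_labels(data.labels, positive)
        if min((y == -1.0).sum(), (y == 1.0).sum()) < 2:
            raise ValidationError("need at least 2 samples per class")
    design = build_design_matrix(data.values, antecedent, mode)
    p = design.shape[1]
    if ridge > 0:
        a = np.vstack([design, np.sqrt(ridge) * np.eye(p)])
        b = np.concatenate([y, np.zeros(p)])
    else:
        a, b = design, y
    coef, *_ = scipy.linalg.lstsq(a, b, lapack_driver="gelsd")
    slices = design_block_slices(antecedent, mode)
    per_rule = [coef[sl] for sl in slices]
    return ConsequentModel(per_rule, mode=mode, ridge=ridge), label_map


def predict_scores(x: np.ndarray, model: TSKClassifier) -> np.ndarray:
    """Real-valued system output p_gᵀ x_g for a batch of inputs."""
    design = build_design_matrix(x, model.antecedent, model.consequent.mode)
    return design @ model.consequent.stacked


def predict_score(x: np.ndarray, model: TSKClassifier) -> float:
    return float(predict_scores(np.asarray(x, dtype=float)[None, :], model)[0])


def rule_outputs(x: np.ndarray, model: TSKClassifier) -> np.ndarray:
    """Per-rule consequent outputs f^k(x) (unweighted), length K."""
    x = np.asarray(x, dtype=float)
    outs = np.empty(model.antecedent.n_rules)
    for k, p in enumerate(model.consequent.coefficients):
        xk = (
            x[model.antecedent.active[k]]
            if model.consequent.mode == "reduced"
            else x
        )
        outs[k] = p[0] + p[1:] @ xk
    return outs


def classify(x: np.ndarray, model: TSKClassifier):
    """Hard label for one input: positive class iff score ≥ 0."""
    return model.positive_label if predict_score(x, model) >= 0 else model.negative_label


def predict_labels(x: np.ndarray, model: TSKClassifier) -> list:
    scores = predict_scores(x, model)
    return [model.positive_label if s >= 0 else model.negative_label for s in scores]


def accuracy(predictions, truths) -> float:
    """Fraction of correctly classified samples."""
    predictions, truths = list(predictions), list(truths)
    if len(truths) == 0:
        raise ValidationError("no samples")
    if len(predictions) != len(truths):
        raise ValidationError("prediction/truth length mismatch")
    return sum(p == t for p, t in zip(predictions, truths)) / len(truths)


# ---------------------------------------------------------------------------
# End-to-end training
# ---------------------------------------------------------------------------


def fit_tsk_classifier(
    data: FeatureMatrix,
    n_rules: int = 15,
    fuzzifier: float = 2.0,
    tolerance: float = 1e-5,
    max_iter: int = 300,
    spread_scale: float = 0.5,
    threshold: float = 0.06,
    ridge: float = 1e-4,
    mode: str = "reduced",
    seed: int = 0,
    positive=None,
) -> TSKClassifier:
    """Full training pipeline.

    Subspace clustering learns the rule centers and the per-rule feature
    weights; the weights are thresholded at τ into activation masks; Gaussian
    antecedent parameters come from the membership-weighted moments; and the
    consequents are one ridge least-squares solve.  Deterministic for a fixed
    seed.
    """
    cfg = ClusteringConfig(
        n_clusters=n_rules,
        fuzzifier=fuzzifier,
        tolerance=tolerance,
        max_iter=max_iter,
        seed=seed,
    )
    clustering = fit_subspace_clustering(data, cfg)
    antecedent = compute_antecedent_parameters(data, clustering, spread_scale)
    mask = activate_features(clustering.weights, threshold)
    antecedent = antecedent.with_mask(mask, threshold)
    logger.info(
        "feature activation at tau=%.3g: per-rule counts %s",
        threshold,
        antecedent.active_counts.tolist(),
    )
    consequent, label_map = fit_consequents(data, antecedent, ridge, mode, positive)
    return TSKClassifier(
        antecedent=antecedent,
        consequent=consequent,
        label_map=label_map,
        feature_names=list(data.feature_names),
        config={
            "n_rules": n_rules,
            "m": fuzzifier,
            "epsilon": tolerance,
            "max_iter": max_iter,
            "h": spread_scale,
            "tau": threshold,
            "lambda": ridge,
            "mode": mode,
            "seed": seed,
        },
    )
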