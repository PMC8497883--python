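"""Rule antecedents: Gaussian membership functions over activated features.

A fitted subspace clustering is turned into one fuzzy rule per cluster.  The
rule's Gaussian center and spread per feature are membership-weighted moments
of the training data, and the cluster's feature weights decide which features
the rule actually mentions: a feature is *active* in rule k when its weight
w_kj reaches the activation threshold τ.  Inactive features drop out of the
rule's antecedent entirely (they contribute a neutral factor of one to the
firing-strength product).
"""

from __future__ import annotations

import numpy as np

from .subspace import ClusteringState, FeatureMatrix, ValidationError

SPREAD_FLOOR = 1e-8


class AntecedentModel:
    """Per-rule Gaussian antecedents with boolean feature-activation masks.

    Parameters
    ----------
    centers, spreads : (K, d) arrays
        Gaussian center and variance-like spread per rule and feature.
        Spreads must be strictly positive wherever the mask is active.
    active : (K, d) bool array
        Which features each rule's antecedent mentions; every rule keeps at
        least one active feature.
    threshold : float in [0, 1)
        The activation threshold τ the mask was derived with.
    spread_scale : float
        The multiplier h applied to the weighted variance when the spreads
        were computed (kept for provenance and serialization).
    """

    def __init__(
        self,
        centers: np.ndarray,
        spreads: np.ndarray,
        active: np.ndarray,
        threshold: float = 0.0,
        spread_scale: float = 0.5,
    ) -> None:
        self.centers = np.asarray(centers, dtype=float)
        self.spreads = np.asarray(spreads, dtype=float)
        self.active = np.asarray(active, dtype=bool)
        self.threshold = float(threshold)
        self.spread_scale = float(spread_scale)
        if self.centers.shape != self.spreads.shape or self.centers.shape != self.active.shape:
            raise ValidationError("antecedent arrays must share a (K, d) shape")
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise ValidationError("need at least one rule")
        if not self.active.any(axis=1).all():
            raise ValidationError("every rule needs at least one active feature")
        if np.any(self.spreads[self.active] <= 0):
            raise ValidationError("invalid spread")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    @property
    def active_counts(self) -> np.ndarray:
        """Number of active features per rule (d_k)."""
        return self.active.sum(axis=1)

    def with_mask(self, active: np.ndarray, threshold: float) -> "AntecedentModel":
        return AntecedentModel(
            self.centers, self.spreads, active, threshold, self.spread_scale
        )

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "spreads": self.spreads.tolist(),
            "active": self.active.astype(int).tolist(),
            "tau": self.threshold,
            "h": self.spread_scale,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AntecedentModel":
        return cls(
            centers=np.asarray(payload["centers"], dtype=float),
            spreads=np.asarray(payload["spreads"], dtype=float),
            active=np.asarray(payload["active"], dtype=bool),
            threshold=float(payload["tau"]),
            spread_scale=float(payload["h"]),
        )


def compute_antecedent_parameters(
    data: FeatureMatrix, clustering: ClusteringState, spread_scale: float = 0.5
) -> AntecedentModel:
    """Membership-weighted Gaussian centers and spreads, all features active.

    Centers are the membership-weighted means of the data (membership
    exponent 1, independent of the clustering fuzzifier); spreads are ``h``
    times the membership-weighted population variance, floored at a tiny
    positive value so constant features stay usable.
    """
    if spread_scale <= 0:
        raise ValidationError("spread_scale must be positive")
    u = clustering.memberships  # (K, N), exponent 1
    mass = u.sum(axis=1)
    if np.any(mass <= 0):
        raise ValidationError("empty rule")
    centers = (u @ data.values) / mass[:, None]
    diff2 = (data.values[None, :, :] - centers[:, None, :]) ** 2
    var = np.einsum("kn,knd->kd", u, diff2) / mass[:, None]
    spreads = np.maximum(spread_scale * var, SPREAD_FLOOR)
    active = np.ones_like(centers, dtype=bool)
    return AntecedentModel(centers, spreads, active, 0.0, spread_scale)


def activate_features(weights: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a cluster feature-weight matrix into a boolean rule mask.

    active[k, j] = (w_kj >= threshold).  If a rule loses every feature, its
    single maximum-weight feature is forced back on (ties broken toward the
    lowest feature index), so every rule keeps at least one antecedent clause.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValidationError("threshold must lie in [0, 1)")
    weights = np.asarray(weights, dtype=float)
    mask = weights >= threshold
    empty = ~mask.any(axis=1)
    if empty.any():
        best = np.argmax(weights[empty], axis=1)  # argmax picks lowest index on ties
        mask[np.flatnonzero(empty), best] = True
    return mask


def membership_value(x: float, center: float, spread: float) -> float:
    """Gaussian membership exp(−(x − center)² / (2·spread)).

    ``spread`` is a variance-like quantity (already scaled by h), so the
    function peaks at 1 on the center and decays with squared distance.
    """
    if spread <= 0:
        raise ValidationError("invalid spread")
    return float(np.exp(-((x - center) ** 2) / (2.0 * spread)))


def log_firing_strengths(x: np.ndarray, model: AntecedentModel) -> np.ndarray:
    """Log of each rule's firing strength at x (active features only)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValidationError("input dimension mismatch")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite input")
    terms = -((x[None, :] - model.centers) ** 2) / (2.0 * model.spreads)
    return np.where(model.active, terms, 0.0).sum(axis=1)


def rule_firing_strengths(
    x: np.ndarray, model: AntecedentModel
) -> tuple[np.ndarray, np.ndarray]:
    """Firing strengths and their normalized form at a single input.

    The product of Gaussian memberships over each rule's active features is
    accumulated in log space; normalization subtracts the max log before
    exponentiating, so heavily mismatched inputs cannot underflow to an
    all-zero vector.  Returns ``(raw, normalized)``; the normalized vector
    sums to one (uniform fallback if every log strength is −inf).
    """
    logs = log_firing_strengths(x, model)
    raw = np.exp(logs)
    finite = np.isfinite(logs)
    if not finite.any():
        k = model.n_rules
        return raw, np.full(k, 1.0 / k)
    shifted = np.exp(logs - logs[finite].max())
    return raw, shifted / shifted.sum()


def normalized_firing_matrix(x: np.ndarray, model: AntecedentModel) -> np.ndarray:
    """Normalized firing strengths for a batch of inputs, shape (N, K)."""
    x = np.asarray(x, dtype=float)
    terms = -((x[:, None, :] - model.centers[None, :, :]) ** 2) / (2.0 * model.spreads)
    logs = np.where(model.active[None, :, :], terms, 0.0).sum(axis=2)  # (N, K)
    shifted = np.exp(logs - logs.max(axis=1, keepdims=True))
    return shifted / shifted.sum(axis=1, keepdims=True)
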