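"""Feature-weighted fuzzy subspace clustering.

Each cluster ``c`` carries, besides its center ``v_c``, a feature-weight
vector ``w_c`` on the probability simplex, so that different clusters can be
compact in different feature subspaces.  The objective is

    J(U, V, W) = sum_c sum_i mu_ci^m * sum_j w_cj (x_ij - v_cj)^2
               + sum_c delta_c * sum_j w_cj^2

subject to columns of U summing to 1 and rows of W summing to 1.  ``delta_c``
is a per-cluster regularizer that keeps the weight vectors away from the
one-hot vertices of the simplex; it is refreshed each sweep from the current
cluster scatter.  The fitted weight matrix is what later drives per-rule
feature activation in the fuzzy classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DELTA_FLOOR = 1e-12
ZERO_DIST = 1e-12


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """A samples-by-features numeric table with optional binary labels.

    Parameters
    ----------
    values : (N, d) float array
        Feature values; all entries must be finite.
    sample_ids : sequence of str, optional
        Defaults to ``s0 .. s{N-1}``.
    feature_names : sequence of str, optional
        Defaults to ``x1 .. xd`` (1-based, matching the rule notation).
    labels : (N,) array, optional
        Class labels; any hashable dtype, two distinct values for training.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        n, d = self.values.shape
        if n < 2:
            raise ValidationError("need at least 2 samples")
        if d < 1:
            raise ValidationError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if not self.feature_names:
            self.feature_names = [f"x{j + 1}" for j in range(d)]
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length mismatch")
        if len(self.feature_names) != d:
            raise ValidationError("feature_names length mismatch")
        if len(set(self.feature_names)) != d:
            raise ValidationError("duplicated feature names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValidationError("labels length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusteringConfig:
    """Hyper-parameters of the subspace clustering.

    ``n_clusters`` equals the number of fuzzy rules of the downstream
    classifier.  ``fuzzifier`` is the usual fuzzy exponent m > 1 (2 by
    default); ``tolerance`` is the absolute change in the objective below
    which iteration stops.
    """

    n_clusters: int = 15
    fuzzifier: float = 2.0
    tolerance: float = 1e-5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be positive")
        if self.fuzzifier <= 1:
            raise ValidationError("fuzzifier must exceed 1")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be positive")


@dataclass
class ClusteringState:
    """Memberships U (C, N), centers V (C, d), weights W (C, d), δ (C,)."""

    memberships: np.ndarray
    centers: np.ndarray
    weights: np.ndarray
    regularizers: np.ndarray
    objective: float = np.nan
    history: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    def to_dict(self) -> dict:
        return {
            "shape": {
                "n_clusters": int(self.centers.shape[0]),
                "n_samples": int(self.memberships.shape[1]),
                "n_features": int(self.centers.shape[1]),
            },
            "memberships": self.memberships.tolist(),
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "regularizers": self.regularizers.tolist(),
            "objective": float(self.objective),
            "history": [float(j) for j in self.history],
            "n_iter": int(self.n_iter),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClusteringState":
        return cls(
            memberships=np.asarray(payload["memberships"], dtype=float),
            centers=np.asarray(payload["centers"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            regularizers=np.asarray(payload["regularizers"], dtype=float),
            objective=float(payload["objective"]),
            history=[float(j) for j in payload.get("history", [])],
            n_iter=int(payload.get("n_iter", 0)),
        )


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def project_rows_to_simplex(rows: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex.

    Uses the standard sort-and-threshold algorithm: entries are shifted by a
    common threshold and clipped at zero so each row sums to one.  A row that
    already lies on the simplex is returned unchanged.
    """
    rows = np.asarray(rows, dtype=float)
    n, d = rows.shape
    srt = np.sort(rows, axis=1)[:, ::-1]
    css = np.cumsum(srt, axis=1) - 1.0
    ks = np.arange(1, d + 1)
    cond = srt - css / ks > 0
    rho = d - np.argmax(cond[:, ::-1], axis=1)  # last index where cond holds
    theta = css[np.arange(n), rho - 1] / rho
    return np.maximum(rows - theta[:, None], 0.0)


def _weighted_sq_distances(
    x: np.ndarray, centers: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """(C, N) matrix of per-cluster feature-weighted squared distances."""
    diff2 = (x[None, :, :] - centers[:, None, :]) ** 2  # (C, N, d)
    return np.einsum("cnd,cd->cn", diff2, weights)


# ---------------------------------------------------------------------------
# Coordinate updates
# ---------------------------------------------------------------------------


def initialize_state(data: FeatureMatrix, config: ClusteringConfig) -> ClusteringState:
    """Seeded initialization: centers sampled from the data, uniform weights.

    Centers are ``C`` distinct rows of the data drawn without replacement by
    squared-distance-weighted (k-means++-style) sampling, which keeps the
    seeds spread out; memberships follow from the membership update under
    the uniform weights; every regularizer starts at 1.
    """
    n, d = data.values.shape
    c = config.n_clusters
    if n < c:
        raise ValidationError("insufficient samples for requested clusters")
    rng = np.random.default_rng(config.seed)
    x = data.values
    idx = [int(rng.integers(n))]
    for _ in range(c - 1):
        dist = np.min(
            [((x - x[i]) ** 2).sum(axis=1) for i in idx], axis=0
        )
        dist[idx] = 0.0
        total = dist.sum()
        if total > 0:
            idx.append(int(rng.choice(n, p=dist / total)))
        else:  # all remaining rows duplicate a chosen seed
            remaining = np.setdiff1d(np.arange(n), idx)
            idx.append(int(remaining[0]))
    centers = x[idx].copy()
    weights = np.full((c, d), 1.0 / d)
    delta = np.ones(c)
    state = ClusteringState(
        memberships=np.zeros((c, n)),
        centers=centers,
        weights=weights,
        regularizers=delta,
    )
    state.memberships = update_memberships(data, state, config)
    state.objective = objective_value(data, state, config)
    return state


def update_feature_weights(
    data: FeatureMatrix, state: ClusteringState, config: ClusteringConfig
) -> np.ndarray:
    """Closed-form weight update followed by projection onto the simplex.

    The unconstrained-in-sign stationary point is

        w_cj = 1/d + (1/(2 δ_c)) Σ_i μ_ci^m ( ||x_i − v_c||²/d − (x_ij − v_cj)² )

    which already sums to one per row.  Because the objective is an isotropic
    quadratic in w_c, the minimizer under w_cj ≥ 0 is the Euclidean projection
    of this point onto the simplex, so negative entries are removed by
    threshold-and-clip rather than division.
    """
    if np.any(state.regularizers <= 0):
        raise ValidationError("degenerate regularizer")
    x, v = data.values, state.centers
    d = x.shape[1]
    um = state.memberships ** config.fuzzifier  # (C, N)
    diff2 = (x[None, :, :] - v[:, None, :]) ** 2  # (C, N, d)
    per_feature = np.einsum("cn,cnd->cd", um, diff2)  # Σ_i μ^m (x_ij − v_cj)²
    total = per_feature.sum(axis=1, keepdims=True)  # Σ_i μ^m ||x_i − v_c||²
    raw = 1.0 / d + (total / d - per_feature) / (2.0 * state.regularizers[:, None])
    return project_rows_to_simplex(raw)


def update_regularizers(
    data: FeatureMatrix, state: ClusteringState, config: ClusteringConfig
) -> np.ndarray:
    """δ_c = weighted within-cluster scatter over the squared-norm of w_c.

    Floored at a tiny positive value so the weight update stays defined when
    every sample sits exactly on its center.
    """
    um = state.memberships ** config.fuzzifier
    dist = _weighted_sq_distances(data.values, state.centers, state.weights)
    scatter = np.einsum("cn,cn->c", um, dist)
    denom = (state.weights**2).sum(axis=1)
    if np.any(denom <= 0):
        raise ValidationError("weight row with zero sum of squares")
    return np.maximum(scatter / denom, DELTA_FLOOR)


def update_memberships(
    data: FeatureMatrix, state: ClusteringState, config: ClusteringConfig
) -> np.ndarray:
    """Fuzzy membership update from the weighted distances.

    A sample lying (numerically) on a center gets crisp membership, split
    equally among tied centers; otherwise the standard power-ratio formula
    applies and each column sums to one.
    """
    dist = _weighted_sq_distances(data.values, state.centers, state.weights)
    c, n = dist.shape
    u = np.zeros((c, n))
    zero_hits = dist < ZERO_DIST  # (C, N)
    singular = zero_hits.any(axis=0)
    if singular.any():
        cols = zero_hits[:, singular]
        u[:, singular] = cols / cols.sum(axis=0, keepdims=True)
    regular = ~singular
    if regular.any():
        dr = dist[:, regular]
        power = 1.0 / (config.fuzzifier - 1.0)
        inv = dr ** (-power)
        u[:, regular] = inv / inv.sum(axis=0, keepdims=True)
    return u


def update_centers(
    data: FeatureMatrix, state: ClusteringState, config: ClusteringConfig
) -> np.ndarray:
    """Membership-weighted mean per cluster.

    The feature weight appears in both numerator and denominator of the
    stationarity condition and cancels; the cancelled form avoids 0/0 for
    features whose weight was clipped to zero.  A cluster with no membership
    mass is reseeded at the sample farthest (in weighted distance) from its
    best center.
    """
    um = state.memberships ** config.fuzzifier  # (C, N)
    mass = um.sum(axis=1)
    centers = np.empty_like(state.centers)
    ok = mass > 0
    centers[ok] = (um[ok] @ data.values) / mass[ok, None]
    if not ok.all():
        dist = _weighted_sq_distances(data.values, state.centers, state.weights)
        farthest = int(np.argmax(dist.min(axis=0)))
        for c_idx in np.flatnonzero(~ok):
            logger.warning("empty cluster %d reseeded from sample %d", c_idx, farthest)
            centers[c_idx] = data.values[farthest]
    return centers


def objective_value(
    data: FeatureMatrix, state: ClusteringState, config: ClusteringConfig
) -> float:
    """Evaluate the clustering objective J at the current state."""
    um = state.memberships ** config.fuzzifier
    dist = _weighted_sq_distances(data.values, state.centers, state.weights)
    scatter = float(np.einsum("cn,cn->", um, dist))
    penalty = float(np.dot(state.regularizers, (state.weights**2).sum(axis=1)))
    return scatter + penalty


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


WARMUP_SWEEPS = 2


def fit_subspace_clustering(
    data: FeatureMatrix, config: ClusteringConfig | None = None
) -> ClusteringState:
    """Alternating minimization with per-cluster constants δ_c set once.

    The fit has three phases.  First, a short warm-up runs membership/center
    sweeps under the uniform feature weights (plain fuzzy c-means on scaled
    distances) so the partition — not the arbitrary seeding — determines the
    regularizer scale.  Second, each δ_c is computed once from that
    partition's scatter and then held fixed: δ_c is a per-cluster constant
    of the objective, and J is strictly increasing in δ, so re-updating it
    inside the loop would break the descent property.  Third, the main loop
    sweeps W → U → V, each an exact coordinate minimizer of J at the fixed
    δ, so the recorded J trajectory is non-increasing; iteration stops when
    the absolute change in J drops below the tolerance or the sweep budget
    is exhausted.
    """
    config = config or ClusteringConfig()
    state = initialize_state(data, config)
    for _ in range(WARMUP_SWEEPS):
        state.memberships = update_memberships(data, state, config)
        state.centers = update_centers(data, state, config)
    state.regularizers = update_regularizers(data, state, config)
    state.objective = objective_value(data, state, config)
    state.history = [state.objective]
    prev = state.objective
    for it in range(1, config.max_iter + 1):
        state.weights = update_feature_weights(data, state, config)
        state.memberships = update_memberships(data, state, config)
        state.centers = update_centers(data, state, config)
        state.objective = objective_value(data, state, config)
        state.history.append(state.objective)
        state.n_iter = it
        if not np.isfinite(state.objective):
            raise ValidationError(f"numerical divergence at iteration {it}")
        if abs(state.objective - prev) < config.tolerance:
            break
        prev = state.objective
    logger.info(
        "subspace clustering converged in %d sweeps, J=%.6g",
        state.n_iter,
        state.objective,
    )
    return state
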