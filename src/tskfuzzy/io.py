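"""Readers/writers, atlas ROI feature extraction, and a stand-in selector.

Feature tables are CSV with one header row of feature names, an optional
label column, and one row per sample; writing uses 17-significant-digit
formatting so a write/read round trip reproduces every float64 bit-exactly.
Models serialize to a single JSON document.  Volumes and label atlases are
NIfTI files on a shared voxel grid (no resampling or registration is
attempted — grids must already be aligned).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .antecedent import AntecedentModel
from .model import ConsequentModel, TSKClassifier
from .subspace import FeatureMatrix, ValidationError

logger = logging.getLogger("tskfuzzy")


def configure_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tskfuzzy")
    root.handlers[:] = [handler]
    root.setLevel(level)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def read_feature_table(path, label_col: str | None = None) -> FeatureMatrix:
    """Read a CSV feature table, optionally splitting off a label column."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"cannot parse CSV {path}: {exc}") from exc
    labels = None
    if label_col is not None:
        if label_col not in frame.columns:
            raise ValidationError(
                f"label column {label_col!r} missing from {path} "
                f"(columns: {list(frame.columns)})"
            )
        labels = frame[label_col].to_numpy()
        frame = frame.drop(columns=[label_col])
    if frame.isna().any().any():
        bad = int(frame.isna().any(axis=1).to_numpy().argmax())
        raise ValidationError(f"missing value in row {bad} of {path}")
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(f"non-numeric feature columns {non_numeric} in {path}")
    return FeatureMatrix(
        values=frame.to_numpy(dtype=float),
        feature_names=[str(c) for c in frame.columns],
        labels=labels,
    )


def write_feature_table(data: FeatureMatrix, path, label_col: str = "label") -> None:
    """Write a feature table as CSV with lossless float formatting."""
    frame = pd.DataFrame(data.values, columns=data.feature_names)
    if data.labels is not None:
        frame[label_col] = data.labels
    frame.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------


def model_to_dict(model: TSKClassifier) -> dict:
    return {
        "antecedent": model.antecedent.to_dict(),
        "consequent": model.consequent.to_dict(),
        "labels": {
            "positive": model.positive_label,
            "negative": model.negative_label,
        },
        "feature_names": list(model.feature_names),
        "config": dict(model.config),
        "software_version": __version__,
    }


def model_from_dict(payload: dict) -> TSKClassifier:
    try:
        labels = payload["labels"]
        return TSKClassifier(
            antecedent=AntecedentModel.from_dict(payload["antecedent"]),
            consequent=ConsequentModel.from_dict(payload["consequent"]),
            label_map={labels["negative"]: -1.0, labels["positive"]: 1.0},
            feature_names=list(payload.get("feature_names", [])),
            config=dict(payload.get("config", {})),
        )
    except KeyError as exc:
        raise ValidationError(f"model JSON missing field {exc}") from exc


def write_model(model: TSKClassifier, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model(path) -> TSKClassifier:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"cannot parse model JSON {path}: {exc}") from exc
    return model_from_dict(payload)


# ---------------------------------------------------------------------------
# Atlas ROI feature extraction
# ---------------------------------------------------------------------------


@dataclass
class RoiFeatureSpec:
    """Which atlas labels to pool and how (only the mean is supported)."""

    region_labels: list = field(default_factory=list)
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if not self.region_labels:
            raise ValidationError("region label list must be non-empty")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValidationError("region labels must be distinct")
        if self.statistic != "mean":
            raise ValidationError("only the mean statistic is supported")


def extract_roi_features(
    volume: np.ndarray, atlas: np.ndarray, spec: RoiFeatureSpec
) -> np.ndarray:
    """Per-region mean intensity for each requested atlas label.

    ``volume`` and ``atlas`` must be pre-aligned grids of identical shape;
    feature j is the mean of the voxels where the atlas equals label j.
    """
    volume = np.asarray(volume, dtype=float)
    atlas = np.asarray(atlas)
    if volume.shape != atlas.shape:
        raise ValidationError(
            f"grids not aligned: volume {volume.shape} vs atlas {atlas.shape}"
        )
    features = np.empty(len(spec.region_labels))
    for j, lab in enumerate(spec.region_labels):
        mask = atlas == lab
        if not mask.any():
            raise ValidationError(f"label {lab} absent from atlas")
        features[j] = volume[mask].mean()
    return features


def extract_roi_features_from_nifti(
    volume_path, atlas_path, spec: RoiFeatureSpec
) -> np.ndarray:
    """Load a NIfTI volume/atlas pair and pool per-region means.

    Only array shapes are compared; affines and orientations are not
    interpreted, so inputs must already share a voxel grid.
    """
    import nibabel as nib

    volume = np.asanyarray(nib.load(str(volume_path)).dataobj)
    atlas = np.asanyarray(nib.load(str(atlas_path)).dataobj).astype(int)
    return extract_roi_features(volume, atlas, spec)


# ---------------------------------------------------------------------------
# Feature-selection stand-in
# ---------------------------------------------------------------------------


def fisher_score_select(
    data: FeatureMatrix, k: int
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Keep the top-k features by between-/within-class variance ratio.

    A deliberately simple univariate filter used as plumbing ahead of the
    classifier.  Features are scored as

        F_j = Σ_c n_c (m_cj − m_j)² / Σ_c n_c s_cj²

    with class means m_cj and within-class variances s_cj²; ties rank the
    lower feature index first; a constant feature scores 0.  Returns the
    reduced table, the selected indices (in original order), and the scores.
    """
    if data.labels is None:
        raise ValidationError("fisher score needs labels")
    classes = sorted(set(data.labels.tolist()))
    if len(classes) != 2:
        raise ValidationError("fisher score needs binary labels")
    if k > data.n_features:
        raise ValidationError("too many features requested")
    if k < 1:
        raise ValidationError("k must be positive")
    overall = data.values.mean(axis=0)
    between = np.zeros(data.n_features)
    within = np.zeros(data.n_features)
    for cls in classes:
        rows = data.values[data.labels == cls]
        between += len(rows) * (rows.mean(axis=0) - overall) ** 2
        within += len(rows) * rows.var(axis=0)
    constant = np.ptp(data.values, axis=0) == 0  # exactly constant columns
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(within > 0, between / np.maximum(within, 1e-300), 0.0)
        scores = np.where(constant | (between == 0), 0.0, scores)
    order = np.lexsort((np.arange(data.n_features), -scores))
    selected = np.sort(order[:k])
    reduced = FeatureMatrix(
        values=data.values[:, selected],
        sample_ids=list(data.sample_ids),
        feature_names=[data.feature_names[j] for j in selected],
        labels=data.labels,
    )
    logger.info("fisher selection kept features %s", selected.tolist())
    return reduced, selected, scores
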