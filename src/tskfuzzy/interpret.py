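"""Linguistic rule-base rendering and the model-complexity count.

Model complexity (MC) is the package's interpretability proxy: the total
number of trainable parameters.  Each active feature of a rule costs two
antecedent parameters (a Gaussian center and spread); each rule's consequent
costs d_k + 1 parameters in reduced mode (its active-feature count plus the
intercept) or d + 1 in full mode.

Linguistic rendering maps each active rule center onto an ordered five-term
scale by min–max normalizing it against the training range of its feature.
Term assignment is inherently a domain-expert judgement; the fixed
equal-width binning here is a deterministic default, and callers may supply
their own scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .antecedent import AntecedentModel
from .model import TSKClassifier
from .subspace import FeatureMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class LinguisticScale:
    """An ordered set of linguistic terms with interior bin edges in [0, 1].

    The default five-term sequence runs Low < Lower < Medium < Higher < High
    — note the unusual ordering of "Low" below "Lower", kept as the package's
    conventional scale.
    """

    terms: tuple = ("Low", "Lower", "Medium", "Higher", "High")
    bin_edges: tuple = (0.2, 0.4, 0.6, 0.8)

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.bin_edges) + 1:
            raise ValidationError("need exactly one more term than bin edge")
        edges = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")

    def term_for(self, position: float) -> str:
        """Term for a normalized position; out-of-range clamps to the ends."""
        position = min(max(position, 0.0), 1.0)
        idx = int(np.searchsorted(self.bin_edges, position, side="left"))
        return self.terms[idx]


@dataclass
class RuleBase:
    """Rendered rules: linguistic clauses plus consequent coefficients."""

    rules: list = field(default_factory=list)
    # each entry: {"index": int, "clauses": [(feature_name, term), ...],
    #             "coefficients": [float, ...]}

    def to_text(self) -> str:
        lines = []
        for rule in self.rules:
            ante = " ∧ ".join(
                f"{feat} is {term}" for feat, term in rule["clauses"]
            )
            coefs = ", ".join(f"{c:.4f}" for c in rule["coefficients"])
            lines.append(f"Rule {rule['index']}: If {ante} then [{coefs}]")
        return "\n".join(lines)

    def to_markdown(self) -> str:
        lines = ["| Rule | Antecedent | Consequent |", "| --- | --- | --- |"]
        for rule in self.rules:
            ante = " ∧ ".join(
                f"{feat} is *{term}*" for feat, term in rule["clauses"]
            )
            coefs = ", ".join(f"{c:.4f}" for c in rule["coefficients"])
            lines.append(f"| {rule['index']} | If {ante} | [{coefs}] |")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "index": r["index"],
                    "clauses": [list(c) for c in r["clauses"]],
                    "coefficients": [round(float(c), 4) for c in r["coefficients"]],
                }
                for r in self.rules
            ]
        }


@dataclass
class ComplexityReport:
    """Per-rule parameter counts and their total."""

    active_counts: list
    antecedent_counts: list
    consequent_counts: list
    mode: str = "reduced"

    @property
    def total(self) -> int:
        return int(sum(self.antecedent_counts) + sum(self.consequent_counts))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "active_counts": [int(v) for v in self.active_counts],
            "antecedent_parameters": [int(v) for v in self.antecedent_counts],
            "consequent_parameters": [int(v) for v in self.consequent_counts],
            "total": self.total,
        }


def assign_linguistic_terms(
    model: AntecedentModel,
    data: FeatureMatrix,
    scale: LinguisticScale | None = None,
) -> list[list[tuple[str, str]]]:
    """Map each active (rule, feature) center to a linguistic term.

    Centers are min–max normalized by the training range of their feature and
    looked up in the scale's bins; centers outside the training range clamp
    to the extreme terms.  A zero-range feature gets the middle term with a
    warning, since its position in the range is undefined.
    """
    scale = scale or LinguisticScale()
    lo = data.values.min(axis=0)
    hi = data.values.max(axis=0)
    span = hi - lo
    middle = scale.terms[len(scale.terms) // 2]
    clauses: list[list[tuple[str, str]]] = []
    for k in range(model.n_rules):
        rule_clauses = []
        for j in np.flatnonzero(model.active[k]):
            name = data.feature_names[j]
            if span[j] == 0:
                logger.warning("feature %s has zero range; using %s", name, middle)
                term = middle
            else:
                term = scale.term_for((model.centers[k, j] - lo[j]) / span[j])
            rule_clauses.append((name, term))
        clauses.append(rule_clauses)
    return clauses


def render_rule_base(
    classifier: TSKClassifier, clauses: list[list[tuple[str, str]]]
) -> RuleBase:
    """Assemble the rule base: one row per rule, stable ordering."""
    if len(clauses) != classifier.antecedent.n_rules:
        raise ValidationError("clause list does not match rule count")
    rules = []
    for k, (rule_clauses, coef) in enumerate(
        zip(clauses, classifier.consequent.coefficients), start=1
    ):
        rules.append(
            {
                "index": k,
                "clauses": list(rule_clauses),
                "coefficients": [float(c) for c in coef],
            }
        )
    return RuleBase(rules=rules)


def model_complexity(
    active: np.ndarray, mode: str = "reduced", n_features: int | None = None
) -> ComplexityReport:
    """Count trainable parameters from a K×d activation mask.

    Antecedents cost 2·d_k per rule; consequents cost d_k + 1 (reduced) or
    d + 1 (full).  ``active`` may also be given as the per-rule active-feature
    counts directly.
    """
    active = np.asarray(active)
    if active.ndim == 2:
        counts = active.astype(bool).sum(axis=1)
        if n_features is None:
            n_features = active.shape[1]
    elif active.ndim == 1:
        counts = active.astype(int)
        if mode == "full" and n_features is None:
            raise ValidationError("full mode needs n_features with count input")
    else:
        raise ValidationError("active must be a mask or a count vector")
    if np.any(counts < 1):
        raise ValidationError("every rule needs at least one active feature")
    if mode not in ("reduced", "full"):
        raise ValidationError("mode must be 'reduced' or 'full'")
    antecedent_counts = [2 * int(dk) for dk in counts]
    if mode == "reduced":
        consequent_counts = [int(dk) + 1 for dk in counts]
    else:
        consequent_counts = [int(n_features) + 1] * len(counts)
    return ComplexityReport(
        active_counts=[int(dk) for dk in counts],
        antecedent_counts=antecedent_counts,
        consequent_counts=consequent_counts,
        mode=mode,
    )
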