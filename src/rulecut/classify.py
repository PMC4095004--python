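"""Class assignment from a rule set, with conflict resolution and weights.

Given an instance x and the set Q of rules whose premise x satisfies:

1. all rules in Q agree -> that class (weights play no role);
2. Q mixes classes -> partition Q into per-class groups Q_i; each feature
   j gets a consistency score t_ij = max relevance R(c) over the
   conditions on j inside Q_i, and the class maximizing
   w_i * sum_j t_ij wins (w_i are optional per-class weights, default 1;
   ties go to the larger unweighted sum, then to vocabulary order);
3. Q is empty -> retry accepting rules violated in at most 1 condition,
   then 2, ... up to the longest premise; if still empty fall back to the
   majority training class with a flag.

An alternative covering-based resolver (t_i = max covering over Q_i) is
available for comparison via ``resolver="covering"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import ExpressionDataset
from .rules import RelevanceTable, Rule, RuleSet

__all__ = ["PredictionResult", "PerformanceMetrics", "matching_rules",
           "assign_class", "predict_dataset", "evaluate", "WEIGHT_PRESETS"]

#: weight configurations mirroring the published weighted-classification sweep
WEIGHT_PRESETS: dict[str, dict[str, float]] = {
    "base": {"Good": 1.0, "Poor": 1.0},
    "balanced": {"Good": 26.0, "Poor": 74.0},  # inverse class proportions
    "bias-poor": {"Good": 1.0, "Poor": 1000.0},
    "bias-good": {"Good": 1000.0, "Poor": 1.0},
}


@dataclass
class PredictionResult:
    assigned_class: str
    matched: dict[str, list[str]]  # class -> rule ids in Q_i
    consistency: dict[str, dict[str, float]]  # t_ij: class -> feature -> score
    relax_depth: int
    conflict: bool
    fallback: bool
    weights: dict[str, float] = field(default_factory=dict)


@dataclass
class PerformanceMetrics:
    """Binary-outcome metrics with an explicit positive class."""

    positive_class: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "recall": self.recall,
                "precision": self.precision, "specificity": self.specificity,
                "npv": self.npv}


def _violations(instance: Mapping[str, float], rule: Rule) -> int:
    for c in rule.conditions:
        if c.feature not in instance:
            raise KeyError(f"instance lacks feature {c.feature!r}")
    return rule.violations(instance)


def matching_rules(instance: Mapping[str, float], ruleset: RuleSet,
                   relax: int = 0) -> list[Rule]:
    """Rules whose premise the instance satisfies, allowing up to ``relax``
    violated conditions."""
    return [r for r in ruleset.rules if _violations(instance, r) <= relax]


def _resolve(ruleset: RuleSet, q_rules: Sequence[Rule],
             relevance: RelevanceTable | None, weights: dict[str, float],
             resolver: str) -> tuple[str, dict, dict, bool]:
    classes_in_q = [c for c in ruleset.classes
                    if any(r.predicted_class == c for r in q_rules)]
    matched = {c: [r.rule_id for r in q_rules if r.predicted_class == c]
               for c in classes_in_q}
    if len(classes_in_q) == 1:
        return classes_in_q[0], matched, {}, False

    # case 2: conflicting matches
    consistency: dict[str, dict[str, float]] = {}
    scores: dict[str, float] = {}
    for cls in classes_in_q:
        t: dict[str, float] = {}
        for r in q_rules:
            if r.predicted_class != cls:
                continue
            for cond in r.conditions:
                if resolver == "covering":
                    val = (r.stats.covering or 0.0) if r.stats else 0.0
                else:
                    if relevance is None:
                        raise ValueError(
                            "conflict resolution needs a relevance table "
                            "(attach one via compute_ruleset_stats)")
                    val = relevance.condition_relevance \
                        .get(r.rule_id, {}).get(cond.feature, 0.0)
                t[cond.feature] = max(t.get(cond.feature, 0.0), val)
        consistency[cls] = t
        scores[cls] = sum(t.values())
    order = {c: i for i, c in enumerate(ruleset.classes)}
    winner = max(classes_in_q,
                 key=lambda c: (scores[c] * weights.get(c, 1.0), scores[c],
                                -order[c]))
    return winner, matched, consistency, True


def assign_class(instance: Mapping[str, float], ruleset: RuleSet,
                 relevance: RelevanceTable | None = None,
                 weights: dict[str, float] | None = None,
                 resolver: str = "relevance") -> PredictionResult:
    """Assign a class to one instance via the three-case procedure."""
    if not ruleset.rules:
        raise ValueError("empty ruleset")
    if resolver not in ("relevance", "covering"):
        raise ValueError(f"unknown resolver {resolver!r}")
    relevance = relevance if relevance is not None else ruleset.relevance
    weights = dict(weights if weights is not None else ruleset.weights or {})

    for depth in range(ruleset.max_premise_length() + 1):
        q = matching_rules(instance, ruleset, relax=depth)
        if q:
            cls, matched, t, conflict = _resolve(ruleset, q, relevance,
                                                 weights, resolver)
            return PredictionResult(cls, matched, t, depth, conflict,
                                    fallback=False, weights=weights)
    fallback_class = ruleset.majority_class or ruleset.classes[0]
    return PredictionResult(fallback_class, {}, {},
                            ruleset.max_premise_length(), conflict=False,
                            fallback=True, weights=weights)


def predict_dataset(ruleset: RuleSet, dataset: ExpressionDataset,
                    weights: dict[str, float] | None = None,
                    resolver: str = "relevance") -> list[PredictionResult]:
    """Classify every sample of a cohort.

    Violation counts are vectorized over the matrix; the per-sample
    three-case logic then works on the precomputed counts.
    """
    if not ruleset.rules:
        raise ValueError("empty ruleset")
    viol = np.zeros((dataset.n, len(ruleset.rules)), dtype=np.int16)
    for k, rule in enumerate(ruleset.rules):
        for c in rule.conditions:
            viol[:, k] += ~np.asarray(c.matches(dataset.column(c.feature)))
    relevance = ruleset.relevance
    weights_d = dict(weights if weights is not None else ruleset.weights or {})
    results = []
    max_len = ruleset.max_premise_length()
    for i in range(dataset.n):
        res = None
        for depth in range(max_len + 1):
            idx = np.flatnonzero(viol[i] <= depth)
            if len(idx):
                q = [ruleset.rules[k] for k in idx]
                cls, matched, t, conflict = _resolve(ruleset, q, relevance,
                                                     weights_d, resolver)
                res = PredictionResult(cls, matched, t, depth, conflict,
                                       fallback=False, weights=weights_d)
                break
        if res is None:
            res = PredictionResult(ruleset.majority_class or ruleset.classes[0],
                                   {}, {}, max_len, False, True, weights_d)
        results.append(res)
    return results


def evaluate(ruleset: RuleSet, dataset: ExpressionDataset,
             weights: dict[str, float] | None = None,
             positive_class: str = "Good",
             resolver: str = "relevance") -> PerformanceMetrics:
    """Cohort-level accuracy/recall/precision/specificity/NPV.

    The positive class (good outcome in the prognostic setting) must be in
    the dataset's label vocabulary.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    if positive_class not in dataset.class_names:
        raise ValueError(f"positive class {positive_class!r} not in label "
                         f"vocabulary {dataset.class_names}")
    preds = [p.assigned_class
             for p in predict_dataset(ruleset, dataset, weights, resolver)]
    y = np.asarray(dataset.labels)
    p = np.asarray(preds)
    pos = y == positive_class
    ppos = p == positive_class
    return PerformanceMetrics(
        positive_class,
        tp=int((ppos & pos).sum()), fp=int((ppos & ~pos).sum()),
        fn=int((~ppos & pos).sum()), tn=int((~ppos & ~pos).sum()))
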