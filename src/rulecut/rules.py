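"""Threshold rules and rule sets.

A rule is a conjunction of threshold (or membership) conditions on feature
values together with a predicted class: ``if <premise> then <class>``.
Rule sets group rules by predicted class and may carry per-rule statistics,
a relevance table and per-class weights used during conflict resolution.
Operator strictness is explicit (``LE`` vs ``LT``) and preserved through
JSON serialization, because published rule sets mix the two forms and
matching semantics must honor them exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

SCHEMA_VERSION = 1


class Op(str, Enum):
    """Condition operators; names are the serialized tokens."""

    LE = "LE"  # x <= t
    LT = "LT"  # x < t
    GT = "GT"  # x > t
    GE = "GE"  # x >= t
    RANGE = "RANGE"  # low < x <= high
    IN = "IN"  # x in {..}


#: operators whose satisfaction region is a lower half-line (low expression)
NEGATIVE_OPS = frozenset({Op.LE, Op.LT})
#: operators whose satisfaction region is an upper half-line (high expression)
POSITIVE_OPS = frozenset({Op.GT, Op.GE})


@dataclass(frozen=True)
class Condition:
    """A single condition on one feature.

    ``threshold`` is used by LE/LT/GT/GE; ``low``/``high`` by RANGE
    (semantics ``low < x <= high``); ``values`` by IN.
    """

    feature: str
    op: Op
    threshold: float | None = None
    low: float | None = None
    high: float | None = None
    values: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "op", Op(self.op))
        if self.op is Op.RANGE:
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"RANGE condition on {self.feature} needs low < high")
            if not (math.isfinite(self.low) and math.isfinite(self.high)):
                raise ValueError("RANGE bounds must be finite")
        elif self.op is Op.IN:
            if not self.values:
                raise ValueError(f"IN condition on {self.feature} needs a non-empty value set")
        else:
            if self.threshold is None or not math.isfinite(self.threshold):
                raise ValueError(f"condition on {self.feature} needs a finite threshold")

    def matches(self, x) -> np.ndarray | bool:
        """Evaluate the condition on a scalar or an array of feature values."""
        x = np.asarray(x)
        if self.op is Op.LE:
            out = x <= self.threshold
        elif self.op is Op.LT:
            out = x < self.threshold
        elif self.op is Op.GT:
            out = x > self.threshold
        elif self.op is Op.GE:
            out = x >= self.threshold
        elif self.op is Op.RANGE:
            out = (x > self.low) & (x <= self.high)
        else:  # IN
            out = np.isin(x, list(self.values))
        return bool(out) if out.ndim == 0 else out

    def describe(self) -> str:
        sym = {Op.LE: "<=", Op.LT: "<", Op.GT: ">", Op.GE: ">="}
        if self.op is Op.RANGE:
            return f"{self.low} < {self.feature} <= {self.high}"
        if self.op is Op.IN:
            return f"{self.feature} in {set(self.values)}"
        return f"{self.feature} {sym[self.op]} {self.threshold:g}"

    def to_dict(self) -> dict:
        d: dict = {"feature": self.feature, "op": self.op.value}
        if self.op is Op.RANGE:
            d.update(low=self.low, high=self.high)
        elif self.op is Op.IN:
            d["values"] = list(self.values)
        else:
            d["threshold"] = self.threshold
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Condition":
        try:
            op = Op(d["op"])
        except ValueError:
            raise ValueError(f"unknown operator token {d.get('op')!r}") from None
        if op is Op.RANGE:
            return cls(d["feature"], op, low=float(d["low"]), high=float(d["high"]))
        if op is Op.IN:
            return cls(d["feature"], op, values=tuple(d["values"]))
        return cls(d["feature"], op, threshold=float(d["threshold"]))


@dataclass
class RuleStats:
    """Per-rule confusion counts and quality ratios on a reference cohort.

    Ratios are ``None`` when their denominator is zero (an explicit
    undefined marker, never silently 0).
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    covering: float | None = None
    error: float | None = None
    precision: float | None = None
    fisher_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "covering": self.covering, "error": self.error,
            "precision": self.precision, "fisher_p": self.fisher_p,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RuleStats":
        return cls(**{k: d.get(k) for k in ("tp", "fp", "fn", "tn", "covering",
                                            "error", "precision", "fisher_p")})


@dataclass
class Rule:
    rule_id: str
    predicted_class: str
    conditions: tuple[Condition, ...]
    stats: RuleStats | None = None

    def __post_init__(self):
        self.conditions = tuple(self.conditions)
        if not self.conditions:
            raise ValueError(f"rule {self.rule_id} has an empty premise")
        feats = [c.feature for c in self.conditions]
        if len(set(feats)) != len(feats):
            raise ValueError(f"rule {self.rule_id} has two conditions on one feature")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(c.feature for c in self.conditions)

    def premise_matches(self, row: Mapping[str, float]) -> bool:
        return all(c.matches(row[c.feature]) for c in self.conditions)

    def violations(self, row: Mapping[str, float]) -> int:
        return sum(0 if c.matches(row[c.feature]) else 1 for c in self.conditions)

    def without(self, condition: Condition) -> "Rule | None":
        """The weakened rule r' with `condition` removed; None if premise empties."""
        remaining = tuple(c for c in self.conditions if c != condition)
        if not remaining:
            return None
        return Rule(self.rule_id + "'", self.predicted_class, remaining)

    def describe(self) -> str:
        prem = " AND ".join(c.describe() for c in self.conditions)
        return f"IF {prem} THEN {self.predicted_class}"

    def to_dict(self) -> dict:
        d = {
            "rule_id": self.rule_id,
            "predicted_class": self.predicted_class,
            "conditions": [c.to_dict() for c in self.conditions],
        }
        if self.stats is not None:
            d["stats"] = self.stats.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Rule":
        stats = RuleStats.from_dict(d["stats"]) if d.get("stats") else None
        return cls(d["rule_id"], d["predicted_class"],
                   tuple(Condition.from_dict(c) for c in d["conditions"]), stats)


@dataclass
class RelevanceTable:
    """Condition- and variable-level relevance.

    ``condition_relevance[rule_id][feature]`` holds R(c) for the condition
    on `feature` in that rule.  ``signed``/``unsigned`` map each class to a
    per-feature relevance; low-expression (<=, <) conditions contribute with
    negative sign, high-expression (>, >=) with positive sign.
    """

    condition_relevance: dict[str, dict[str, float]] = field(default_factory=dict)
    signed: dict[str, dict[str, float]] = field(default_factory=dict)
    unsigned: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition_relevance": self.condition_relevance,
            "signed": self.signed,
            "unsigned": self.unsigned,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RelevanceTable":
        return cls(
            {k: dict(v) for k, v in d.get("condition_relevance", {}).items()},
            {k: dict(v) for k, v in d.get("signed", {}).items()},
            {k: dict(v) for k, v in d.get("unsigned", {}).items()},
        )


@dataclass
class RuleSet:
    """An ordered collection of rules partitioned into per-class groups."""

    rules: list[Rule]
    classes: tuple[str, ...] = ()
    relevance: RelevanceTable | None = None
    weights: dict[str, float] | None = None
    majority_class: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rules = list(self.rules)
        if not self.classes:
            seen: list[str] = []
            for r in self.rules:
                if r.predicted_class not in seen:
                    seen.append(r.predicted_class)
            self.classes = tuple(seen)
        if self.weights is not None:
            bad = [c for c, w in self.weights.items() if not w > 0]
            if bad:
                raise ValueError(f"non-positive weights for classes {bad}")
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rule ids")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def group(self, cls: str) -> list[Rule]:
        """The class group G_i (possibly empty)."""
        return [r for r in self.rules if r.predicted_class == cls]

    @property
    def class_groups(self) -> dict[str, list[Rule]]:
        return {c: self.group(c) for c in self.classes}

    @property
    def features(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.rules:
            for f in r.features:
                if f not in seen:
                    seen.append(f)
        return tuple(seen)

    def max_premise_length(self) -> int:
        return max(len(r.conditions) for r in self.rules) if self.rules else 0

    def to_dict(self) -> dict:
        d: dict = {
            "schema_version": SCHEMA_VERSION,
            "classes": list(self.classes),
            "rules": [r.to_dict() for r in self.rules],
        }
        if self.relevance is not None:
            d["relevance"] = self.relevance.to_dict()
        if self.weights is not None:
            d["weights"] = dict(self.weights)
        if self.majority_class is not None:
            d["majority_class"] = self.majority_class
        if self.metadata:
            d["metadata"] = self.metadata
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RuleSet":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version > SCHEMA_VERSION:
            raise ValueError(f"unsupported ruleset schema version {version}")
        return cls(
            rules=[Rule.from_dict(r) for r in d["rules"]],
            classes=tuple(d.get("classes", ())),
            relevance=RelevanceTable.from_dict(d["relevance"]) if d.get("relevance") else None,
            weights=dict(d["weights"]) if d.get("weights") else None,
            majority_class=d.get("majority_class"),
            metadata=dict(d.get("metadata", {})),
        )

    def to_json(self, path=None, **json_kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **json_kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RuleSet":
        """Parse a ruleset from a JSON string or a file path."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed ruleset JSON: {exc}") from exc
        return cls.from_dict(d)
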