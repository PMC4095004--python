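"""Synthetic expression cohorts with planted rule structure.

The generator emulates the study design every other module is exercised
against: a two-class cohort (about 74% good / 26% poor outcome by
default), d continuous MAS5-like features of which a small informative
subset is dichotomized by planted thresholds, labels produced by running a
planted rule set through the real classifier (then optionally flipped to
emulate annotation noise), and class-dependent exponential survival with
uniform plus administrative censoring.

Informative feature values are drawn from two right-skewed log-normal
components on either side of the planted threshold, so the threshold sits
in a genuine low/high expression gap; uninformative features are
class-independent log-normal noise.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .classify import assign_class
from .dataset import ExpressionDataset
from .rules import Condition, Op, RelevanceTable, Rule, RuleSet

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "generate_survival",
           "make_planted_rules"]

_MAX_INFORMATIVE = 15  # pattern space is enumerated: 2^f patterns


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated design: 182 patients, 62 probe sets,
    11 informative ones carrying up to 9 planted rules of at most two
    conditions, a 74/26 good/poor split, and survival separating the
    classes at the 5-year endpoint.
    """

    seed: int
    n: int = 182
    d: int = 62
    rules: RuleSet | None = None
    n_informative: int = 11
    n_rules: int = 9
    max_conditions: int = 2
    class_probs: dict[str, float] = field(
        default_factory=lambda: {"Good": 0.74, "Poor": 0.26})
    coherence: float = 0.9
    flip_rate: float = 0.0
    noise_scale: float = 0.25
    # survival: events per year; Good outcome mostly alive at 5 years,
    # Poor mostly dead
    hazards: dict[str, float] = field(
        default_factory=lambda: {"Good": 0.03, "Poor": 0.35})
    censor_rate: float = 0.15
    horizon: float = 10.0  # years of administrative follow-up

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if not 0.0 <= self.flip_rate < 0.5:
            raise ValueError("flip rate must lie in [0, 0.5)")
        if not 0.5 <= self.coherence <= 1.0:
            raise ValueError("coherence must lie in [0.5, 1]")
        if any(h <= 0 for h in self.hazards.values()):
            raise ValueError("hazards must be positive")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_probs)


@dataclass
class GroundTruth:
    rules: RuleSet
    informative_features: list[str]
    thresholds: dict[str, float]
    pre_flip_labels: list[str]
    flipped: np.ndarray  # bool mask of flipped samples


def _feature_ids(d: int) -> list[str]:
    return [f"ps_{i:04d}_at" for i in range(1, d + 1)]


def make_planted_rules(features: list[str], thresholds: dict[str, float],
                       classes: tuple[str, ...], n_rules: int,
                       max_conditions: int, rng: np.random.Generator) -> RuleSet:
    """Random planted rule set in the published style.

    Each rule conjoins 1..max_conditions dichotomizing conditions on
    distinct informative features; the first class's rules use
    low-expression (<=) conditions and later classes high-expression (>)
    conditions, mirroring the good-outcome-low / poor-outcome-high pattern
    of hypoxia signatures.  Synthetic condition relevances are attached so
    conflicting matches resolve deterministically.
    """
    rules = []
    # every informative feature appears in at least one rule; premises are
    # drawn from a shuffled cycle so features recur once n_rules*conds > f
    pool = list(rng.permutation(features))
    for k in range(n_rules):
        cls_i = int(k % len(classes)) if k < 2 * len(classes) else \
            int(rng.integers(len(classes)))
        cls = classes[cls_i]
        n_cond = min(int(rng.integers(1, max_conditions + 1)), len(features))
        feats: list[str] = []
        while len(feats) < n_cond:
            if not pool:
                pool = list(rng.permutation(features))
            f = pool.pop()
            if f not in feats:
                feats.append(f)
        op = Op.LE if cls_i == 0 else Op.GT
        conds = tuple(Condition(f, op, threshold=thresholds[f]) for f in feats)
        rules.append(Rule(str(k + 1), cls, conds))
    rs = RuleSet(rules, classes=classes)
    rel = RelevanceTable()
    for r in rules:
        rel.condition_relevance[r.rule_id] = {
            c.feature: float(rng.uniform(0.2, 0.9)) for c in r.conditions}
    rs.relevance = rel
    rs.majority_class = classes[0]
    return rs


def _attach_synthetic_relevance(rs: RuleSet, rng: np.random.Generator) -> None:
    """Condition relevances for conflict resolution, derived from the rule
    set's own signed table when present, else drawn at random (synthetic)."""
    if rs.relevance is not None and rs.relevance.condition_relevance:
        return
    rel = rs.relevance or RelevanceTable()
    for r in rs.rules:
        rel.condition_relevance[r.rule_id] = {}
        for c in r.conditions:
            signed = (rel.signed.get(r.predicted_class, {}) or {})
            val = abs(signed.get(c.feature, 0.0)) or float(rng.uniform(0.2, 0.9))
            rel.condition_relevance[r.rule_id][c.feature] = val
    rs.relevance = rel


def _pattern_classes(rs: RuleSet, features: list[str],
                     thresholds: dict[str, float], margin: float,
                     ) -> dict[str, list[tuple[int, ...]]]:
    """Classify every low/high side pattern of the informative features.

    Side patterns are turned into concrete values just clear of each
    threshold and pushed through the real classifier, so labels are by
    construction what the planted rules predict.
    """
    f = len(features)
    if f > _MAX_INFORMATIVE:
        raise ValueError(f"at most {_MAX_INFORMATIVE} informative features "
                         f"(pattern space is enumerated)")
    by_class: dict[str, list[tuple[int, ...]]] = {c: [] for c in rs.classes}
    for pattern in itertools.product((0, 1), repeat=f):
        row = {feat: thresholds[feat] * (np.exp(margin) if side else np.exp(-margin))
               for feat, side in zip(features, pattern)}
        res = assign_class(row, rs)
        by_class[res.assigned_class].append(pattern)
    return by_class


def _typical_sides(rs: RuleSet, features: list[str]) -> dict[str, dict[str, float]]:
    """Class-typical side per informative feature.

    A class's own rules fix its typical side (<= / < conditions point low,
    > / >= high); features a class never conditions on default to the
    opposite of the other classes' typical side, emulating outcome-coherent
    marker panels where every informative probe set tracks the same latent
    axis.  0.5 marks no preference.
    """
    demanded: dict[str, dict[str, float]] = {c: {} for c in rs.classes}
    for r in rs.rules:
        for c in r.conditions:
            if c.feature not in features:
                continue
            side = 0.0 if c.op in (Op.LE, Op.LT) else 1.0
            cur = demanded[r.predicted_class].get(c.feature)
            demanded[r.predicted_class][c.feature] = \
                side if cur is None or cur == side else 0.5
    out: dict[str, dict[str, float]] = {}
    for cls in rs.classes:
        out[cls] = {}
        for f in features:
            t = demanded[cls].get(f)
            if t is None:
                others = [demanded[o][f] for o in rs.classes
                          if o != cls and f in demanded[o]
                          and demanded[o][f] != 0.5]
                t = 1.0 - others[0] if others else 0.5
            out[cls][f] = t
    return out


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one cohort; deterministic per seed.

    Raises if a planted rule references a feature outside the matrix.
    Sampling is by latent class: a class is drawn from ``class_probs``, a
    low/high side pattern is drawn among the patterns the planted rules
    classify as that class -- weighted so each feature shows its
    class-typical side with probability ``coherence`` -- and expression
    values are drawn on the chosen sides.  Labels therefore equal the
    planted-rule classification exactly before flipping.
    """
    rng = np.random.default_rng(spec.seed)
    margin = 0.05
    feature_ids = _feature_ids(spec.d)

    if spec.rules is not None:
        rs = spec.rules
        informative = list(rs.features)
        missing = [f for f in informative if f not in feature_ids]
        if missing:
            if len(informative) > spec.d:
                raise ValueError("planted rules reference more features than d")
            # embed the rule set's own feature ids into the matrix
            feature_ids = informative + \
                [f for f in _feature_ids(spec.d) if f not in informative][
                    : spec.d - len(informative)]
        thresholds = {}
        for r in rs.rules:
            for c in r.conditions:
                if c.op in (Op.LE, Op.LT, Op.GT, Op.GE):
                    thresholds.setdefault(c.feature, float(c.threshold))
                else:
                    raise ValueError("planted rules must use threshold conditions")
        _attach_synthetic_relevance(rs, rng)
    else:
        informative = feature_ids[: spec.n_informative]
        thresholds = {f: float(np.exp(rng.uniform(np.log(10), np.log(2000))))
                      for f in informative}
        rs = make_planted_rules(informative, thresholds, spec.classes,
                                spec.n_rules, spec.max_conditions, rng)

    by_class = _pattern_classes(rs, informative, thresholds, margin)
    typical = _typical_sides(rs, informative)
    pattern_weights: dict[str, np.ndarray] = {}
    for cls in spec.classes:
        pats = by_class.get(cls, [])
        w = np.array([
            np.prod([spec.coherence if side == typical[cls][f]
                     else 0.5 if typical[cls][f] == 0.5
                     else 1.0 - spec.coherence
                     for f, side in zip(informative, p)])
            for p in pats])
        if not len(w) or w.sum() <= 0:
            raise ValueError(
                f"planted rules admit no pattern for class {cls!r} at "
                f"coherence {spec.coherence}; cannot hit the requested "
                f"class probabilities")
        pattern_weights[cls] = w / w.sum()

    classes = spec.classes
    probs = np.array([spec.class_probs[c] for c in classes])
    latent_idx = rng.choice(len(classes), size=spec.n, p=probs)
    labels = [classes[i] for i in latent_idx]

    values = np.empty((spec.n, len(feature_ids)))
    info_pos = {f: feature_ids.index(f) for f in informative}
    uninf = [j for j, f in enumerate(feature_ids) if f not in informative]
    # uninformative: class-independent right-skewed noise
    values[:, uninf] = rng.lognormal(mean=np.log(100.0), sigma=1.0,
                                     size=(spec.n, len(uninf)))
    for i, cls in enumerate(labels):
        patterns = by_class[cls]
        pattern = patterns[int(rng.choice(len(patterns), p=pattern_weights[cls]))]
        for f, side in zip(informative, pattern):
            theta = thresholds[f]
            eps = margin + abs(rng.normal(0.0, spec.noise_scale))
            values[i, info_pos[f]] = theta * np.exp(eps if side else -eps)

    pre_flip = list(labels)
    flip_mask = rng.random(spec.n) < spec.flip_rate
    flipped_labels = list(labels)
    others = {c: [o for o in classes if o != c] for c in classes}
    for i in np.flatnonzero(flip_mask):
        alts = others[flipped_labels[i]]
        flipped_labels[i] = alts[int(rng.integers(len(alts)))]

    ds = ExpressionDataset(
        [f"s{i + 1:04d}" for i in range(spec.n)], feature_ids, values,
        labels=flipped_labels)
    return ds, GroundTruth(rs, list(informative), thresholds, pre_flip,
                           flip_mask)


def generate_survival(labels, spec: CohortSpec,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Class-dependent exponential event times with censoring.

    Event times are exponential with the class hazard.  A ``censor_rate``
    fraction of samples is lost to follow-up at a Uniform time before its
    event (so ``censor_rate`` is the expected dropout fraction exactly),
    and everyone still under observation is administratively censored at
    ``horizon`` years.  Returns (observed time, event indicator).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    labels = list(labels)
    n = len(labels)
    t_event = np.array([rng.exponential(1.0 / spec.hazards[y]) for y in labels])
    time = np.minimum(t_event, spec.horizon)
    event = (t_event <= spec.horizon).astype(int)
    dropout = rng.random(n) < spec.censor_rate
    u = rng.random(n)
    time = np.where(dropout, u * time, time)
    event = np.where(dropout, 0, event)
    return time, event.astype(int)


def generate_cohort_with_survival(spec: CohortSpec,
                                  ) -> tuple[ExpressionDataset, GroundTruth]:
    """Cohort plus survival columns driven by the (pre-flip) class."""
    ds, gt = generate_cohort(spec)
    time, event = generate_survival(gt.pre_flip_labels, spec)
    ds.survival_time = np.asarray(time, float)
    ds.survival_event = np.asarray(event, int)
    return ds, gt
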