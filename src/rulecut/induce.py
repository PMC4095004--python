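"""Overlapping rule induction on discretized data.

The learner follows an aggregative (bottom-up) covering policy: for each
class, repeatedly seed a maximally specific rule from a still-uncovered
example whose discretized pattern is most frequent among the class's
uncovered examples, then generalize it by greedily deleting the condition
whose removal gains the most covering while the rule's error stays within
the ``max_error`` budget.  Rules from different seeds may overlap; every
training example ends up covered by at least one rule of its own class.
The error budget itself is selected by repeated stratified k-fold
cross-validation over a small grid.

Conditions are emitted in the original feature units: bin 0 of a
dichotomized feature becomes ``x <= gamma``, bin 1 becomes ``x > gamma``,
and interior bins of multi-cutoff features become range conditions
``gamma_b < x <= gamma_{b+1}``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import evaluate
from .dataset import ExpressionDataset
from .discretize import CutoffSet, adid_discretize, apply_cutoffs
from .metrics import compute_ruleset_stats
from .rules import Condition, Op, Rule, RuleSet

__all__ = ["InductionConfig", "induce_rules", "exhaustive_best_rule",
           "select_max_error", "fit_model"]

DEFAULT_GRID = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass
class InductionConfig:
    """Induction and cross-validation settings.

    max_error: cap on a rule's training error E(r) during generalization.
    grid/folds/repeats/seed: the cross-validated selection of max_error.
    prune_dominated: drop rules whose premise is a superset of another
        same-class rule with no covering gain.
    s_fraction: separation multiplicity fraction for the discretizer.
    """

    max_error: float = 0.25
    grid: tuple[float, ...] = DEFAULT_GRID
    folds: int = 10
    repeats: int = 10
    seed: int = 42
    prune_dominated: bool = True
    s_fraction: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.max_error <= 1.0:
            raise ValueError("max_error must lie in [0, 1]")
        if any(not 0.0 <= g <= 1.0 for g in self.grid):
            raise ValueError("grid values must lie in [0, 1]")
        if self.folds < 2:
            raise ValueError("need k >= 2 folds")


# ---------------------------------------------------------------------------
# conditions from bins

def _bin_condition(feature: str, b: int, gammas: np.ndarray) -> Condition:
    if b == 0:
        return Condition(feature, Op.LE, threshold=float(gammas[0]))
    if b == len(gammas):
        return Condition(feature, Op.GT, threshold=float(gammas[-1]))
    return Condition(feature, Op.RANGE, low=float(gammas[b - 1]),
                     high=float(gammas[b]))


def _cutoff_features(dataset: ExpressionDataset, cutoffs: CutoffSet,
                     ) -> list[tuple[int, str, np.ndarray]]:
    """(column index, feature id, gamma array) for features with cutoffs,
    in dataset column order."""
    out = []
    for j, f in enumerate(dataset.feature_ids):
        g = cutoffs.values_for(f)
        if len(g):
            out.append((j, f, g))
    return out


# ---------------------------------------------------------------------------
# induction

def _rule_counts(mask: np.ndarray, is_cls: np.ndarray) -> tuple[float, float]:
    """(covering, error) of a premise mask; 0 for empty denominators."""
    npos = int(is_cls.sum())
    nneg = int((~is_cls).sum())
    cov = float((mask & is_cls).sum()) / npos if npos else 0.0
    err = float((mask & ~is_cls).sum()) / nneg if nneg else 0.0
    return cov, err


def induce_rules(dataset: ExpressionDataset, cutoffs: CutoffSet,
                 config: InductionConfig | None = None,
                 max_error: float | None = None) -> RuleSet:
    """Induce an overlapping rule set under the max-error constraint.

    Returns a RuleSet with per-rule statistics and a relevance table
    computed on the training cohort, and the majority training class
    recorded for prediction-time fallback.
    """
    if dataset.labels is None:
        raise ValueError("induction needs labels")
    config = config or InductionConfig()
    e_max = config.max_error if max_error is None else max_error
    feats = _cutoff_features(dataset, cutoffs)
    if not feats:
        raise ValueError("no discretized features: cutoff set is empty")
    bins = apply_cutoffs(dataset, cutoffs)
    cols = [j for j, _, _ in feats]
    pat = bins[:, cols]  # n x n_cutoff_features pattern matrix
    # column masks per (feature position, bin) for fast premise evaluation
    y = np.asarray(dataset.labels)

    rules: list[Rule] = []
    rid = itertools.count(1)
    for cls in dataset.class_names:
        is_cls = y == cls
        if not is_cls.any():
            warnings.warn(f"class {cls!r} has no examples; no rules induced")
            continue
        covered = np.zeros(dataset.n, dtype=bool)
        while True:
            uncovered = np.flatnonzero(is_cls & ~covered)
            if not len(uncovered):
                break
            # seed: uncovered example with the most frequent pattern among
            # uncovered class examples; tie -> lowest sample index
            pats = [tuple(pat[i]) for i in uncovered]
            counts: dict[tuple, int] = {}
            for p in pats:
                counts[p] = counts.get(p, 0) + 1
            best_count = max(counts.values())
            seed_i = next(i for i, p in zip(uncovered, pats)
                          if counts[p] == best_count)

            active = list(range(len(feats)))  # positions of kept conditions
            mask = np.all(pat == pat[seed_i], axis=1)
            cov, err = _rule_counts(mask, is_cls)
            # greedy generalization by condition deletion
            while len(active) > 1:
                best = None
                for pos in active:
                    rest = [p for p in active if p != pos]
                    m = np.all(pat[:, rest] == pat[seed_i, rest], axis=1)
                    c2, e2 = _rule_counts(m, is_cls)
                    if e2 <= e_max + 1e-12:
                        # prefer max covering gain, then lowest relevance of
                        # the deleted condition (= lowest weakened error),
                        # then lowest feature index
                        key = (-c2, (e2 - err) * cov, feats[pos][0])
                        if best is None or key < best[0]:
                            best = (key, pos, m, c2, e2)
                if best is None:
                    break
                _, pos, mask, cov, err = best
                active.remove(pos)
            conds = tuple(_bin_condition(feats[p][1], int(pat[seed_i, p]),
                                         feats[p][2]) for p in active)
            rules.append(Rule(str(next(rid)), cls, conds))
            covered |= mask & is_cls

    if config.prune_dominated:
        rules = _prune_dominated(rules, dataset)
    ruleset = RuleSet(rules, classes=dataset.class_names)
    return compute_ruleset_stats(ruleset, dataset)


def _prune_dominated(rules: list[Rule], dataset: ExpressionDataset) -> list[Rule]:
    """Drop rules whose condition set strictly contains another same-class
    rule's conditions without covering more (duplicates keep the first)."""
    from .metrics import rule_confusion

    keys = [frozenset((c.feature, c.op, c.threshold, c.low, c.high, c.values)
                      for c in r.conditions) for r in rules]
    cov = []
    for r in rules:
        tp, fp, fn, tn = rule_confusion(r, dataset)
        cov.append(tp / (tp + fn) if tp + fn else 0.0)
    keep = []
    for i, r in enumerate(rules):
        dominated = False
        for k, other in enumerate(rules):
            if k == i or other.predicted_class != r.predicted_class:
                continue
            if keys[k] < keys[i] and cov[i] <= cov[k]:
                dominated = True
                break
            if keys[k] == keys[i] and k < i:
                dominated = True
                break
        if not dominated:
            keep.append(r)
    return keep


# ---------------------------------------------------------------------------
# exhaustive oracle

def exhaustive_best_rule(dataset: ExpressionDataset, cutoffs: CutoffSet,
                         target_class: str, max_error: float,
                         max_conditions: int = 2,
                         max_enumeration: int = 200_000) -> Rule | None:
    """The max-covering rule over at most ``max_conditions`` conditions with
    E(r) <= max_error, by full enumeration (test oracle).

    Ties prefer fewer conditions, then the lexicographically first
    (feature-index, bin) combination.  Returns None when no enumerated rule
    meets the error budget.  Refuses oversized instances.
    """
    if dataset.labels is None:
        raise ValueError("needs labels")
    feats = _cutoff_features(dataset, cutoffs)
    bins = apply_cutoffs(dataset, cutoffs)
    y = np.asarray(dataset.labels)
    is_cls = y == target_class
    n_bins = [len(g) + 1 for _, _, g in feats]
    total = 0
    for k in range(1, max_conditions + 1):
        for combo in itertools.combinations(range(len(feats)), k):
            prod = 1
            for p in combo:
                prod *= n_bins[p]
            total += prod
    if total > max_enumeration:
        raise ValueError(f"instance too large for enumeration ({total} rules)")

    best = None
    for k in range(1, max_conditions + 1):
        for combo in itertools.combinations(range(len(feats)), k):
            for assignment in itertools.product(*(range(n_bins[p]) for p in combo)):
                mask = np.ones(dataset.n, dtype=bool)
                for p, b in zip(combo, assignment):
                    mask &= bins[:, feats[p][0]] == b
                cov, err = _rule_counts(mask, is_cls)
                if err <= max_error + 1e-12:
                    key = (-cov, k, combo, assignment)
                    if best is None or key < best[0]:
                        best = (key, combo, assignment)
    if best is None:
        return None
    _, combo, assignment = best
    conds = tuple(_bin_condition(feats[p][1], b, feats[p][2])
                  for p, b in zip(combo, assignment))
    return Rule("oracle", target_class, conds)


# ---------------------------------------------------------------------------
# cross-validated selection of the error budget

def select_max_error(dataset: ExpressionDataset,
                     config: InductionConfig | None = None,
                     ) -> tuple[float, pd.DataFrame]:
    """Pick max_error by repeated stratified k-fold cross-validation.

    Every fold re-runs the discretizer and the rule learner on its training
    part and scores accuracy on the held-out part.  Returns the grid value
    with the highest mean accuracy (ties to the smaller value) and the full
    mean +/- sd table.
    """
    if dataset.labels is None:
        raise ValueError("needs labels")
    config = config or InductionConfig()
    if dataset.n < config.folds:
        raise ValueError("fewer samples than folds")
    y = np.asarray(dataset.labels)
    acc: dict[float, list[float]] = {g: [] for g in config.grid}
    for rep in range(config.repeats):
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                              random_state=config.seed + rep)
        for train_idx, val_idx in skf.split(np.zeros(dataset.n), y):
            train = dataset.subset(train_idx)
            val = dataset.subset(val_idx)
            cutoffs = adid_discretize(train, s_fraction=config.s_fraction)
            for g in config.grid:
                model = induce_rules(train, cutoffs, config, max_error=g)
                m = evaluate(model, val,
                             positive_class=train.class_names[0])
                acc[g].append(m.accuracy)
    table = pd.DataFrame({
        "max_error": list(config.grid),
        "mean_accuracy": [float(np.mean(acc[g])) for g in config.grid],
        "sd_accuracy": [float(np.std(acc[g], ddof=1)) for g in config.grid],
    })
    best = min(config.grid,
               key=lambda g: (-round(float(np.mean(acc[g])), 12), g))
    return best, table


def fit_model(dataset: ExpressionDataset, config: InductionConfig | None = None,
              select: bool = False) -> tuple[RuleSet, CutoffSet, pd.DataFrame | None]:
    """Discretize then induce; optionally cross-validate max_error first."""
    config = config or InductionConfig()
    table = None
    if select:
        best, table = select_max_error(dataset, config)
        config = InductionConfig(max_error=best, grid=config.grid,
                                 folds=config.folds, repeats=config.repeats,
                                 seed=config.seed,
                                 prune_dominated=config.prune_dominated,
                                 s_fraction=config.s_fraction)
    cutoffs = adid_discretize(dataset, s_fraction=config.s_fraction)
    model = induce_rules(dataset, cutoffs, config)
    return model, cutoffs, table
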