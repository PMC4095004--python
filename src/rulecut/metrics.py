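"""Rule quality and relevance statistics.

For a rule r predicting class y, evaluated on a labeled cohort:

* TP/FP: class-y / other-class samples satisfying the whole premise;
  FN/TN: class-y / other-class samples violating at least one condition.
* covering  C(r) = TP / (TP + FN)   -- generality on the target class
* error     E(r) = FP / (FP + TN)   -- leakage from other classes
* precision P(r) = TP / (TP + FP)
* Fisher exact p: significance of the premise/class association (one-sided
  enrichment by default; rules are directional claims).

Condition relevance R(c) = (E(r') - E(r)) * C(r), where r' drops c from the
premise; weakening a premise can only add matches, so R(c) >= 0.  Per-class
variable relevance combines the R(c) of every condition a class's rules
place on a feature, with low-expression conditions (<=, <) contributing a
negative sign and high-expression conditions (>, >=) a positive one.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import fisher_exact

from .dataset import ExpressionDataset
from .rules import (NEGATIVE_OPS, POSITIVE_OPS, Condition, Op, RelevanceTable,
                    Rule, RuleSet, RuleStats)

__all__ = [
    "premise_mask", "rule_confusion", "rule_quality", "fisher_p",
    "condition_relevance", "variable_relevance", "rank_features",
    "compute_ruleset_stats",
]


def premise_mask(rule: Rule, dataset: ExpressionDataset) -> np.ndarray:
    """Boolean mask of samples satisfying every condition of the premise."""
    mask = np.ones(dataset.n, dtype=bool)
    for c in rule.conditions:
        mask &= np.asarray(c.matches(dataset.column(c.feature)))
    return mask


def rule_confusion(rule: Rule, dataset: ExpressionDataset) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) of a rule on a labeled cohort."""
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    match = premise_mask(rule, dataset)
    is_cls = np.asarray(dataset.labels) == rule.predicted_class
    tp = int((match & is_cls).sum())
    fp = int((match & ~is_cls).sum())
    fn = int((~match & is_cls).sum())
    tn = int((~match & ~is_cls).sum())
    return tp, fp, fn, tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def rule_quality(tp: int, fp: int, fn: int, tn: int,
                 ) -> tuple[float | None, float | None, float | None]:
    """(covering, error, precision); None marks a zero denominator."""
    return _ratio(tp, tp + fn), _ratio(fp, fp + tn), _ratio(tp, tp + fp)


def fisher_p(tp: int, fp: int, fn: int, tn: int, two_sided: bool = False) -> float:
    """Exact p-value for the premise/class 2x2 table.

    One-sided by default: the hypergeometric upper tail for enrichment of
    the target class among premise-satisfying samples.
    """
    alternative = "two-sided" if two_sided else "greater"
    return float(fisher_exact([[tp, fp], [fn, tn]], alternative=alternative)[1])


def condition_relevance(rule: Rule, condition: Condition,
                        dataset: ExpressionDataset) -> float:
    """R(c) = (E(r') - E(r)) * C(r) with r' = rule minus the condition.

    For a single-condition rule, r' is the always-true premise and E(r') is
    computed on it (1 whenever any non-class sample exists).  Degenerate
    cohorts with an undefined C or E yield 0.
    """
    if condition not in rule.conditions:
        raise ValueError("condition does not belong to the rule")
    tp, fp, fn, tn = rule_confusion(rule, dataset)
    cov, err, _ = rule_quality(tp, fp, fn, tn)
    if cov is None or err is None:
        return 0.0
    weaker = rule.without(condition)
    if weaker is None:
        # always-true premise: every sample matches
        err_w = _ratio(fp + tn, fp + tn)
    else:
        tp2, fp2, fn2, tn2 = rule_confusion(weaker, dataset)
        err_w = _ratio(fp2, fp2 + tn2)
    if err_w is None:
        return 0.0
    return (err_w - err) * cov


def _condition_sign_factors(cond: Condition, r: float) -> tuple[float, float]:
    """(negative-product factor, positive-product factor) for one condition.

    <=/< conditions are low-expression claims (negative side); >/>= are
    high-expression (positive side).  A RANGE condition carries both a
    lower and an upper bound and contributes its factor to both sides;
    IN conditions have no direction and are treated as positive.
    """
    f = 1.0 - r
    if cond.op in NEGATIVE_OPS:
        return f, 1.0
    if cond.op in POSITIVE_OPS or cond.op is Op.IN:
        return 1.0, f
    return f, f  # RANGE


def variable_relevance(ruleset: RuleSet, dataset: ExpressionDataset,
                       target_class: str,
                       condition_r: dict[str, dict[str, float]] | None = None,
                       ) -> dict[str, dict[str, float]]:
    """Signed and unsigned per-feature relevance for one class's rule group.

    unsigned R_v(x_j) = 1 - prod(1 - R(c)) over the group's conditions on
    x_j; signed R_v = prod_neg(1 - R) - prod_pos(1 - R), so a feature used
    only in low-expression conditions gets -R_v and only high-expression
    gets +R_v.  Features absent from the group score 0.  Returns
    ``{"signed": {...}, "unsigned": {...}}`` over all dataset features.

    ``condition_r`` may supply precomputed R(c) values keyed by
    rule id -> feature.
    """
    signed = {f: 0.0 for f in dataset.feature_ids}
    unsigned = {f: 0.0 for f in dataset.feature_ids}
    neg_prod = {f: 1.0 for f in dataset.feature_ids}
    pos_prod = {f: 1.0 for f in dataset.feature_ids}
    all_prod = {f: 1.0 for f in dataset.feature_ids}
    touched: set[str] = set()
    for rule in ruleset.group(target_class):
        for cond in rule.conditions:
            if condition_r is not None:
                r = condition_r[rule.rule_id][cond.feature]
            else:
                r = condition_relevance(rule, cond, dataset)
            nf, pf = _condition_sign_factors(cond, r)
            neg_prod[cond.feature] *= nf
            pos_prod[cond.feature] *= pf
            all_prod[cond.feature] *= 1.0 - r
            touched.add(cond.feature)
    for f in touched:
        signed[f] = neg_prod[f] - pos_prod[f]
        unsigned[f] = 1.0 - all_prod[f]
    return {"signed": signed, "unsigned": unsigned}


def rank_features(relevance: RelevanceTable) -> list[str]:
    """Features ordered by descending max |signed R_v| across classes.

    Zero-relevance features keep their input order; other ties break by
    feature id.
    """
    feats: list[str] = []
    for per_class in relevance.signed.values():
        for f in per_class:
            if f not in feats:
                feats.append(f)
    score = {f: max(abs(per_class.get(f, 0.0))
                    for per_class in relevance.signed.values())
             for f in feats}
    order = {f: i for i, f in enumerate(feats)}
    return sorted(feats, key=lambda f: (-score[f], f if score[f] > 0 else "",
                                        order[f]))


def compute_ruleset_stats(ruleset: RuleSet, dataset: ExpressionDataset,
                          two_sided_fisher: bool = False) -> RuleSet:
    """Attach confusion counts, C/E/P, Fisher p and a relevance table.

    Statistics are computed on the given (training) cohort and frozen into
    the returned RuleSet; rules and ordering are unchanged.
    """
    cond_rel: dict[str, dict[str, float]] = {}
    rules = []
    for rule in ruleset.rules:
        tp, fp, fn, tn = rule_confusion(rule, dataset)
        cov, err, prec = rule_quality(tp, fp, fn, tn)
        stats = RuleStats(tp, fp, fn, tn, cov, err, prec,
                          fisher_p(tp, fp, fn, tn, two_sided=two_sided_fisher))
        cond_rel[rule.rule_id] = {
            c.feature: condition_relevance(rule, c, dataset)
            for c in rule.conditions}
        rules.append(replace(rule, stats=stats))
    classes = ruleset.classes or dataset.class_names
    out = RuleSet(rules, classes=classes, weights=ruleset.weights,
                  majority_class=ruleset.majority_class,
                  metadata=dict(ruleset.metadata))
    table = RelevanceTable(condition_relevance=cond_rel)
    for cls in classes:
        rv = variable_relevance(out, dataset, cls, condition_r=cond_rel)
        table.signed[cls] = rv["signed"]
        table.unsigned[cls] = rv["unsigned"]
    out.relevance = table
    if out.majority_class is None and dataset.labels is not None:
        names = list(dataset.class_names)
        counts = {c: dataset.labels.count(c) for c in names}
        out.majority_class = max(names, key=lambda c: (counts[c], -names.index(c)))
    return out
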