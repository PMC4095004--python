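"""Rule confusion counts, quality ratios, Fisher p and relevance."""

from math import comb

import numpy as np
import pytest

import rulecut as rc
from rulecut.rules import Condition, Op, Rule, RuleSet


def make_ds(values, labels, feature_ids=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return rc.ExpressionDataset(
        [f"s{i}" for i in range(len(values))],
        feature_ids or [f"f{j}" for j in range(values.shape[1])],
        values, labels=labels)


def random_labeled_ds(rng, n):
    d = int(rng.integers(1, 4))
    ds = make_ds(rng.integers(0, 8, size=(n, d)).astype(float),
                 [str(rng.choice(["Good", "Poor"])) for _ in range(n)])
    return ds if len(set(ds.labels)) == 2 else random_labeled_ds(rng, n)


def random_rule(rng, ds):
    feats = list(rng.choice(ds.feature_ids,
                            size=int(rng.integers(1, ds.d + 1)),
                            replace=False))
    ops = [Op.LE, Op.LT, Op.GT, Op.GE]
    conds = tuple(
        Condition(f, ops[int(rng.integers(len(ops)))],
                  threshold=float(rng.integers(0, 8))) for f in feats)
    return Rule("r", str(rng.choice(["Good", "Poor"])), conds)


class TestConfusion:
    def test_rule_matching_nothing(self):
        ds = make_ds([1, 2, 3], ["Good", "Good", "Poor"])
        r = Rule("r", "Good", (Condition("f0", Op.GT, threshold=99),))
        assert rc.rule_confusion(r, ds) == (0, 0, 2, 1)

    def test_always_true_premise(self):
        ds = make_ds([1, 2, 3], ["Good", "Good", "Poor"])
        r = Rule("r", "Good", (Condition("f0", Op.GT, threshold=-1),))
        tp, fp, fn, tn = rc.rule_confusion(r, ds)
        assert (fn, tn) == (0, 0)

    def test_counts_match_per_sample_enumeration(self):
        """Vectorized confusion equals brute-force row-by-row evaluation."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            ds = random_labeled_ds(rng, int(rng.integers(4, 21)))
            r = random_rule(rng, ds)
            tp = fp = fn = tn = 0
            for i in range(ds.n):
                m = all(c.matches(ds.values[i, ds.feature_index(c.feature)])
                        for c in r.conditions)
                same = ds.labels[i] == r.predicted_class
                tp += m and same
                fp += m and not same
                fn += (not m) and same
                tn += (not m) and not same
            assert rc.rule_confusion(r, ds) == (tp, fp, fn, tn)

    def test_strictness_honored(self):
        ds = make_ds([5, 5.0001], ["Good", "Poor"])
        le = Rule("r", "Good", (Condition("f0", Op.LE, threshold=5),))
        lt = Rule("r", "Good", (Condition("f0", Op.LT, threshold=5),))
        assert rc.rule_confusion(le, ds)[0] == 1
        assert rc.rule_confusion(lt, ds)[0] == 0

    def test_missing_feature_rejected(self):
        ds = make_ds([1], ["Good"])
        r = Rule("r", "Good", (Condition("zz", Op.LE, threshold=1),))
        with pytest.raises(KeyError):
            rc.rule_confusion(r, ds)


class TestQualityRatios:
    def test_printed_formulas(self):
        cov, err, prec = rc.rule_quality(4, 1, 1, 9)
        assert (cov, err, prec) == (0.8, 0.1, 0.8)

    def test_zero_denominators_are_undefined_markers(self):
        cov, err, prec = rc.rule_quality(0, 0, 0, 5)
        assert cov is None and prec is None
        assert err == 0.0

    def test_fixture_rule_7_published_quality(self, fixture_rules):
        r7 = next(r for r in fixture_rules if r.rule_id == "7")
        assert r7.stats.covering == pytest.approx(0.92)
        assert r7.stats.error == pytest.approx(0.17)


class TestFisher:
    def test_perfect_split_exact_value(self):
        # 5 matches all target among 5/5: p = 1 / C(10, 5)
        assert rc.fisher_p(5, 0, 0, 5) == pytest.approx(1 / comb(10, 5))

    def test_association_free_table_not_significant(self):
        assert rc.fisher_p(2, 2, 2, 2) > 0.05

    def test_matches_hypergeometric_tail_enumeration(self):
        """One-sided p equals the sum over all tables with the same margins
        and at least the observed overlap."""
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(4, 21))
            tp = int(rng.integers(0, n + 1))
            fp = int(rng.integers(0, n - tp + 1))
            fn = int(rng.integers(0, n - tp - fp + 1))
            tn = n - tp - fp - fn
            k, m, nn = tp + fn, tp + fp, n  # class size, matches, total
            tail = sum(comb(k, x) * comb(nn - k, m - x)
                       for x in range(tp, min(k, m) + 1)
                       if m - x <= nn - k) / comb(nn, m)
            assert rc.fisher_p(tp, fp, fn, tn) == pytest.approx(tail)


class TestRelevance:
    def test_zero_when_removal_changes_nothing(self):
        ds = make_ds([[1, 1], [2, 1], [9, 9]], ["Good", "Good", "Poor"])
        r = Rule("r", "Good", (Condition("f0", Op.LE, threshold=5),
                               Condition("f1", Op.LE, threshold=5)))
        # both conditions exclude exactly the Poor sample; dropping either
        # leaves the matched set unchanged
        assert rc.condition_relevance(r, r.conditions[0], ds) == 0.0

    def test_formula_value(self):
        # C = 1, E goes 0 -> 0.5 on removal: R = 0.5
        ds = make_ds([[1, 1], [2, 1], [1, 9], [9, 9]],
                     ["Good", "Good", "Poor", "Poor"])
        r = Rule("r", "Good", (Condition("f0", Op.LE, threshold=5),
                               Condition("f1", Op.LE, threshold=5)))
        assert rc.condition_relevance(r, r.conditions[1], ds) \
            == pytest.approx(0.5)

    def test_single_condition_rule_uses_always_true_weakening(self):
        ds = make_ds([1, 9], ["Good", "Poor"])
        r = Rule("r", "Good", (Condition("f0", Op.LE, threshold=5),))
        # r' matches everything: E(r') = 1, E(r) = 0, C(r) = 1
        assert rc.condition_relevance(r, r.conditions[0], ds) \
            == pytest.approx(1.0)

    def test_never_negative_on_random_rules(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            ds = random_labeled_ds(rng, int(rng.integers(4, 15)))
            r = random_rule(rng, ds)
            for c in r.conditions:
                assert rc.condition_relevance(r, c, ds) >= 0.0

    def test_matches_definition_by_independent_recomputation(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            ds = random_labeled_ds(rng, 12)
            r = random_rule(rng, ds)
            for c in r.conditions:
                tp, fp, fn, tn = rc.rule_confusion(r, ds)
                cov = tp / (tp + fn) if tp + fn else None
                err = fp / (fp + tn) if fp + tn else None
                weaker = r.without(c)
                if weaker is None:
                    err_w = 1.0 if fp + tn else None
                else:
                    t2, f2, n2, u2 = rc.rule_confusion(weaker, ds)
                    err_w = f2 / (f2 + u2) if f2 + u2 else None
                expected = 0.0 if None in (cov, err, err_w) \
                    else (err_w - err) * cov
                assert rc.condition_relevance(r, c, ds) \
                    == pytest.approx(expected)


class TestVariableRelevance:
    def _single_condition_setup(self, op):
        ds = make_ds([[1], [9]], ["Good", "Poor"])
        r = Rule("r", "Good", (Condition("f0", op, threshold=5),))
        rs = RuleSet([r], classes=("Good", "Poor"))
        return ds, rs

    def test_low_expression_condition_contributes_negative(self):
        ds, rs = self._single_condition_setup(Op.LE)
        rv = rc.variable_relevance(rs, ds, "Good")
        r = rc.condition_relevance(rs.rules[0], rs.rules[0].conditions[0], ds)
        assert rv["signed"]["f0"] == pytest.approx(-r)
        assert rv["unsigned"]["f0"] == pytest.approx(r)

    def test_high_expression_condition_contributes_positive(self):
        ds = make_ds([[9], [1]], ["Good", "Poor"])
        r = Rule("r", "Good", (Condition("f0", Op.GT, threshold=5),))
        rs = RuleSet([r], classes=("Good", "Poor"))
        rv = rc.variable_relevance(rs, ds, "Good")
        rr = rc.condition_relevance(r, r.conditions[0], ds)
        assert rv["signed"]["f0"] == pytest.approx(rr)

    def test_absent_feature_scores_zero(self):
        ds, rs = self._single_condition_setup(Op.LE)
        ds2 = make_ds([[1, 3], [9, 4]], ["Good", "Poor"])
        rv = rc.variable_relevance(rs, ds2, "Good")
        assert rv["signed"]["f1"] == 0.0

    def test_unsigned_equals_abs_signed_for_one_direction(self, fixture_cohort):
        ds, _ = fixture_cohort
        rs = rc.compute_ruleset_stats(rc.load_nb_hypo_ii(), ds)
        for cls in ("Good", "Poor"):
            for rule in rs.group(cls):
                for cond in rule.conditions:
                    f = cond.feature
                    directions = {c.op in (Op.LE, Op.LT)
                                  for r in rs.group(cls)
                                  for c in r.conditions if c.feature == f}
                    if len(directions) == 1:
                        assert abs(rs.relevance.signed[cls][f]) \
                            == pytest.approx(rs.relevance.unsigned[cls][f])


class TestRanking:
    def test_fixture_table_top_feature(self, fixture_rules):
        order = rc.rank_features(fixture_rules.relevance)
        assert order[0] == "217356_s_at"  # |0.92| dominates

    def test_all_zero_table_keeps_input_order(self):
        table = rc.RelevanceTable(signed={"Good": {"b": 0.0, "a": 0.0}})
        assert rc.rank_features(table) == ["b", "a"]

    def test_permutation_invariance_of_nonzero_ranking(self, fixture_rules):
        signed = fixture_rules.relevance.signed
        fwd = rc.rank_features(rc.RelevanceTable(signed=signed))
        rev = rc.RelevanceTable(signed={
            cls: dict(reversed(list(v.items()))) for cls, v in signed.items()})
        assert rc.rank_features(rev) == fwd
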