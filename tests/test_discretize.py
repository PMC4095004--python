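"""Cutoff selection: ladders, constraints, greedy solver, baselines."""

import numpy as np
import pytest

import rulecut as rc
from rulecut.discretize import fulfills_constraints
from conftest import random_small_dataset


def make_ds(values, labels, feature_ids=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return rc.ExpressionDataset(
        [f"s{i}" for i in range(len(values))],
        feature_ids or [f"f{j}" for j in range(values.shape[1])],
        values, labels=labels)


class TestLadder:
    def test_distinct_sorted_values_and_slots(self):
        ds = make_ds([1, 1, 2, 5], ["A", "A", "B", "B"])
        lad = rc.build_ladder(ds)
        assert lad.values[0].tolist() == [1, 2, 5]
        assert lad.n_slots(0) == 2

    def test_constant_feature_has_no_slots(self):
        lad = rc.build_ladder(make_ds([3, 3, 3], ["A", "B", "A"]))
        assert lad.n_slots(0) == 0

    def test_order_invariance(self):
        a = rc.build_ladder(make_ds([5, 2, 1, 1], ["A", "A", "B", "B"]))
        b = rc.build_ladder(make_ds([1, 1, 2, 5], ["A", "A", "B", "B"]))
        assert a.values[0].tolist() == b.values[0].tolist()


class TestConstraints:
    def test_s_from_fraction_of_dimensions(self):
        ds = make_ds(np.arange(20).reshape(2, 10), ["A", "B"])
        cons = rc.build_constraints(ds, s_fraction=0.2)
        assert cons.s == 2

    def test_s_floor_of_one(self):
        ds = make_ds([1, 2], ["A", "B"])
        assert rc.build_constraints(ds, s_fraction=0.2).s == 1

    def test_identical_rows_excluded_with_warning(self):
        ds = make_ds([[1, 2], [1, 2], [3, 4]], ["A", "B", "B"])
        with pytest.warns(UserWarning, match="unsatisfiable"):
            cons = rc.build_constraints(ds)
        assert cons.n_unsatisfiable == 1
        assert cons.n_pairs == 1  # only the separable pair remains

    def test_single_class_rejected(self):
        ds = make_ds([1, 2], ["A", "A"])
        with pytest.raises(ValueError, match="two classes"):
            rc.build_constraints(ds)


class TestGreedy:
    def test_single_gap_yields_one_cutoff_between_clusters(self, gap_dataset):
        cs = rc.adid_discretize(gap_dataset, s=1)
        assert cs.total == 1
        (c,) = cs.cutoffs["f1"]
        assert 2 < c.value < 5

    def test_xor_needs_one_cutoff_per_feature(self, xor_dataset):
        cs = rc.adid_discretize(xor_dataset, s=1)
        assert cs.total == 2
        assert cs.counts() == {"f1": 1, "f2": 1}
        opt, _ = rc.brute_force_min_cutoffs(xor_dataset, s=1)
        assert opt == 2

    def test_inseparable_classes_raise(self):
        ds = make_ds([[1.0], [1.0]], ["A", "B"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="not separable"):
                rc.adid_discretize(ds)

    def test_deterministic_given_tie_policy(self, xor_dataset):
        a = rc.adid_discretize(xor_dataset, s=1).to_dict()
        b = rc.adid_discretize(xor_dataset, s=1).to_dict()
        assert a == b

    def test_random_instances_fulfilled_minimal_and_bounded(self):
        """Greedy output separates every satisfiable pair, is
        inclusion-minimal, and never beats the exhaustive optimum (with
        equality whenever the optimum is a single cutoff)."""
        rng = np.random.default_rng(2024)
        for _ in range(30):
            ds = random_small_dataset(rng)
            try:
                cs = rc.adid_discretize(ds, s=1)
            except ValueError:
                continue  # inseparable instance
            assert fulfills_constraints(cs, ds, s=1)
            # inclusion-minimal: removing any single cutoff breaks a pair
            for f, cl in cs.cutoffs.items():
                for drop in cl:
                    pruned = rc.CutoffSet({
                        g: [c for c in dl if not (g == f and c == drop)]
                        for g, dl in cs.cutoffs.items()})
                    assert not fulfills_constraints(pruned, ds, s=1)
            opt, _ = rc.brute_force_min_cutoffs(ds, s=1)
            assert cs.total >= opt
            if opt == 1:
                assert cs.total == 1

    def test_separation_completeness_after_discretization(self):
        """Every satisfiable cross-class pair lands in different bins."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            ds = random_small_dataset(rng)
            try:
                cs = rc.adid_discretize(ds)
            except ValueError:
                continue
            bins = rc.apply_cutoffs(ds, cs)
            y = np.asarray(ds.labels)
            for u in range(ds.n):
                for v in range(u + 1, ds.n):
                    if y[u] == y[v] or np.array_equal(ds.values[u],
                                                      ds.values[v]):
                        continue
                    assert not np.array_equal(bins[u], bins[v])


class TestRefinement:
    def test_midpoint_placement(self, gap_dataset):
        cs = rc.adid_discretize(gap_dataset, s=1)
        assert cs.cutoffs["f1"][0].value == pytest.approx(3.5)

    def test_integer_granularity_midpoint(self):
        ds = make_ds([700, 720, 722, 730], ["A", "A", "B", "B"])
        cs = rc.adid_discretize(ds, s=1)
        assert cs.cutoffs["f0"][0].value == pytest.approx(721)

    def test_refinement_preserves_training_bins(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ds = random_small_dataset(rng)
            try:
                raw = rc.adid_discretize(ds, refine=False)
            except ValueError:
                continue
            refined = rc.refine_cutoffs(raw, rc.build_ladder(ds))
            assert np.array_equal(rc.apply_cutoffs(ds, raw),
                                  rc.apply_cutoffs(ds, refined))


class TestApplyCutoffs:
    def test_left_closed_convention(self):
        ds = make_ds([721, 722], ["A", "B"])
        cs = rc.CutoffSet({"f0": [rc.discretize.Cutoff(721.0, 0)]})
        bins = rc.apply_cutoffs(ds, cs)
        assert bins[:, 0].tolist() == [0, 1]  # 721 below, 722 above

    def test_feature_without_cutoffs_is_single_bin(self):
        ds = make_ds([[1, 9], [2, 3]], ["A", "B"])
        cs = rc.CutoffSet({"f0": [rc.discretize.Cutoff(1.5, 0)]})
        assert rc.apply_cutoffs(ds, cs)[:, 1].tolist() == [0, 0]

    def test_missing_feature_rejected(self):
        ds = make_ds([1, 2], ["A", "B"])
        cs = rc.CutoffSet({"nope": [rc.discretize.Cutoff(1.5, 0)]})
        with pytest.raises(KeyError):
            rc.apply_cutoffs(ds, cs)


class TestBaselines:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4], 2.5),
        ([1, 1, 1, 9], 5.0),  # snapped to the only slot midpoint
    ])
    def test_equal_frequency_cutoff(self, values, expected):
        assert rc.equal_frequency_cutoff(values) == pytest.approx(expected)

    def test_equal_frequency_rejects_constant(self):
        with pytest.raises(ValueError):
            rc.equal_frequency_cutoff([2, 2, 2])

    def test_youden_perfect_separation(self):
        cut, direction, j = rc.roc_youden_cutoff(
            [1, 2, 10, 11], ["A", "A", "B", "B"], positive_label="B")
        assert 2 < cut < 10
        assert direction == "high"
        assert j == pytest.approx(1.0)

    def test_youden_no_signal_returns_lowest_slot(self):
        values = [1, 2, 3, 4, 1, 2, 3, 4]
        labels = ["A"] * 4 + ["B"] * 4
        cut, _, j = rc.roc_youden_cutoff(values, labels)
        assert j == pytest.approx(0.0)
        assert cut == pytest.approx(1.5)

    def test_youden_matches_exhaustive_enumeration(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        labels = np.array(["A", "A", "B", "A", "B", "B", "A", "B"])
        cut, direction, j = rc.roc_youden_cutoff(values, labels,
                                                 positive_label="B")
        best = -np.inf
        pos = labels == "B"
        for m in (values[:-1] + values[1:]) / 2:
            for call in (values > m, values <= m):
                jj = (call & pos).sum() / pos.sum() \
                    + (~call & ~pos).sum() / (~pos).sum() - 1
                best = max(best, jj)
        assert j == pytest.approx(best)

    def test_youden_rejects_single_class(self):
        with pytest.raises(ValueError):
            rc.roc_youden_cutoff([1, 2], ["A", "A"])
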