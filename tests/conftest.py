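import numpy as np
import pytest

import rulecut as rc


@pytest.fixture
def gap_dataset():
    """One feature, class A at {1, 2}, class B at {5, 6}: a single
    separating gap between 2 and 5."""
    return rc.ExpressionDataset(
        ["a", "b", "c", "d"], ["f1"],
        np.array([[1.0], [2.0], [5.0], [6.0]]),
        labels=["A", "A", "B", "B"])


@pytest.fixture
def xor_dataset():
    """Two features in an XOR layout: no single cutoff separates, two do."""
    return rc.ExpressionDataset(
        ["a", "b", "c", "d"], ["f1", "f2"],
        np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]]),
        labels=["A", "A", "B", "B"])


@pytest.fixture
def fixture_rules():
    return rc.load_nb_hypo_ii()


@pytest.fixture
def fixture_cohort():
    """Cohort generated by planting the packaged 9 rules (thresholds as
    planted cutoffs), with light label noise."""
    spec = rc.CohortSpec(seed=5, n=150, d=62, rules=rc.load_nb_hypo_ii(),
                         flip_rate=0.03)
    ds, gt = rc.generate_cohort(spec)
    return ds, gt


def random_small_dataset(rng, max_n=6, max_d=3, max_total_slots=20):
    """Small labeled instance with a bounded candidate-slot count."""
    while True:
        n = int(rng.integers(3, max_n + 1))
        d = int(rng.integers(1, max_d + 1))
        values = rng.integers(0, 6, size=(n, d)).astype(float)
        labels = [str(rng.choice(["A", "B"])) for _ in range(n)]
        if len(set(labels)) < 2:
            continue
        ds = rc.ExpressionDataset([f"s{i}" for i in range(n)],
                                  [f"f{j}" for j in range(d)], values,
                                  labels=labels)
        ladder = rc.build_ladder(ds)
        if ladder.total_slots == 0 or ladder.total_slots > max_total_slots:
            continue
        return ds
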