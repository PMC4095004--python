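"""Supervised multivariate discretization.

The central object is a minimum-cutoff covering problem: place as few
cutoffs as possible on the features' value axes so that every pair of
training samples from different classes ends up in different discrete bins
on at least ``s`` feature slots (the s-reinforced separation constraint,
with s = 0.2 d by default).  The greedy attribute-driven solver adds, at
each step, the candidate cutoff slot that separates the largest number of
still-unfulfilled constraint units, then prunes redundant cutoffs so the
result is inclusion-minimal, and finally refines each cutoff to the
midpoint of its slot (which never changes any training sample's bin).

Baselines (median/equal-frequency and ROC/Youden single cutoffs) and an
exhaustive brute-force solver (the test oracle for the integer program) are
also provided.

Bin convention is left-closed: a value x falls in the bin below a cutoff
gamma when x <= gamma, matching the "<= / >" condition pair of published
dichotomized rules.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset

__all__ = [
    "ValueLadder", "Cutoff", "CutoffSet", "SeparationConstraintSet",
    "build_ladder", "build_constraints", "adid_discretize", "refine_cutoffs",
    "apply_cutoffs", "brute_force_min_cutoffs", "equal_frequency_cutoff",
    "roc_youden_cutoff",
]


# ---------------------------------------------------------------------------
# value ladders and cutoff sets

@dataclass
class ValueLadder:
    """Per-feature sorted distinct observed values.

    Feature j with alpha_j distinct values offers alpha_j - 1 candidate
    cutoff slots; slot l (0-based) is the open interval between the l-th
    and (l+1)-th distinct values.
    """

    feature_ids: list[str]
    values: list[np.ndarray]  # strictly ascending per feature

    def n_slots(self, j: int) -> int:
        return len(self.values[j]) - 1

    @property
    def total_slots(self) -> int:
        return sum(self.n_slots(j) for j in range(len(self.feature_ids)))

    def slot_bounds(self, j: int, slot: int) -> tuple[float, float]:
        v = self.values[j]
        return float(v[slot]), float(v[slot + 1])

    def slot_midpoint(self, j: int, slot: int) -> float:
        lo, hi = self.slot_bounds(j, slot)
        return (lo + hi) / 2.0


@dataclass(frozen=True)
class Cutoff:
    value: float
    slot: int  # slot index in the feature's ladder
    quality: float | None = None  # greedy quality at selection time


@dataclass
class CutoffSet:
    """Per-feature ordered cutoff lists with slot provenance."""

    cutoffs: dict[str, list[Cutoff]] = field(default_factory=dict)

    def __post_init__(self):
        for f, cl in self.cutoffs.items():
            vals = [c.value for c in cl]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"cutoffs for {f} not strictly increasing")

    def counts(self) -> dict[str, int]:
        """t_j: number of cutoffs per feature."""
        return {f: len(cl) for f, cl in self.cutoffs.items()}

    @property
    def total(self) -> int:
        return sum(len(cl) for cl in self.cutoffs.values())

    def values_for(self, feature: str) -> np.ndarray:
        return np.array([c.value for c in self.cutoffs.get(feature, [])])

    def to_dict(self) -> dict:
        return {"schema_version": 1, "cutoffs": {
            f: [{"value": c.value, "slot": c.slot, "quality": c.quality} for c in cl]
            for f, cl in self.cutoffs.items()}}

    @classmethod
    def from_dict(cls, d) -> "CutoffSet":
        return cls({f: [Cutoff(c["value"], c["slot"], c.get("quality")) for c in cl]
                    for f, cl in d["cutoffs"].items()})


# ---------------------------------------------------------------------------
# constraints

@dataclass
class SeparationConstraintSet:
    """s-reinforced separation constraints over cross-class sample pairs.

    For pair (u, v) and feature j the eligible slot set X_juv is the
    contiguous range of ladder slots whose cutoff lies strictly between
    x_uj and x_vj; stored as half-open rank ranges ``lo[p, j]:hi[p, j]``.
    Each satisfiable pair must accumulate at least
    ``min(s, total eligible slots)`` selected cutoffs across features.
    Pairs with identical feature vectors are unsatisfiable and excluded
    (with a warning) since no cutoff can separate them.
    """

    pairs: list[tuple[int, int]]  # sample index pairs (u, v), satisfiable only
    lo: np.ndarray  # (n_pairs, d) int32 slot range start per feature
    hi: np.ndarray  # (n_pairs, d) int32 slot range end (exclusive)
    demand: np.ndarray  # (n_pairs,) required cutoff multiplicity
    s: int
    n_unsatisfiable: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def available(self) -> np.ndarray:
        """Total eligible slots |union_j X_juv| per pair."""
        return (self.hi - self.lo).sum(axis=1)


def build_ladder(dataset: ExpressionDataset) -> ValueLadder:
    """Sorted distinct observed values per feature."""
    return ValueLadder(list(dataset.feature_ids),
                       [np.unique(dataset.values[:, j]) for j in range(dataset.d)])


def build_constraints(dataset: ExpressionDataset, ladder: ValueLadder | None = None,
                      s_fraction: float = 0.2, s: int | None = None,
                      ) -> SeparationConstraintSet:
    """Build one separation constraint per unordered cross-class pair.

    ``s`` defaults to ``max(1, ceil(s_fraction * d))``; pass ``s`` explicitly
    to override the fraction rule.
    """
    if dataset.labels is None or len(dataset.class_names) < 2:
        raise ValueError("separation constraints need at least two classes")
    if ladder is None:
        ladder = build_ladder(dataset)
    if s is None:
        s = max(1, math.ceil(s_fraction * dataset.d))

    y = np.asarray(dataset.labels)
    # rank of each sample's value in its feature ladder
    ranks = np.empty((dataset.n, dataset.d), dtype=np.int32)
    for j in range(dataset.d):
        ranks[:, j] = np.searchsorted(ladder.values[j], dataset.values[:, j])

    classes = dataset.class_names
    pairs: list[tuple[int, int]] = []
    for a, b in itertools.combinations(range(len(classes)), 2):
        ia = np.flatnonzero(y == classes[a])
        ib = np.flatnonzero(y == classes[b])
        pairs.extend((int(u), int(v)) for u in ia for v in ib)

    if not pairs:
        raise ValueError("no cross-class sample pairs")
    pu = np.array([p[0] for p in pairs])
    pv = np.array([p[1] for p in pairs])
    lo = np.minimum(ranks[pu], ranks[pv])
    hi = np.maximum(ranks[pu], ranks[pv])  # half-open slot range [lo, hi)
    avail = (hi - lo).sum(axis=1)
    sat = avail > 0
    n_unsat = int((~sat).sum())
    if n_unsat:
        bad = [(dataset.sample_ids[pairs[i][0]], dataset.sample_ids[pairs[i][1]])
               for i in np.flatnonzero(~sat)[:3]]
        warnings.warn(
            f"{n_unsat} cross-class pair(s) with identical feature vectors are "
            f"unsatisfiable and were excluded (e.g. {bad})")
    keep = np.flatnonzero(sat)
    return SeparationConstraintSet(
        pairs=[pairs[i] for i in keep],
        lo=lo[keep], hi=hi[keep],
        demand=np.minimum(s, avail[keep]).astype(np.int64),
        s=s, n_unsatisfiable=n_unsat)


# ---------------------------------------------------------------------------
# greedy solver

def _slot_offsets(ladder: ValueLadder) -> np.ndarray:
    sizes = [ladder.n_slots(j) for j in range(len(ladder.feature_ids))]
    return np.concatenate([[0], np.cumsum(sizes)])


def _selection_to_cutoffset(selected: list[tuple[int, int, float | None]],
                            ladder: ValueLadder) -> CutoffSet:
    """Build a CutoffSet placing each cutoff at its slot's lower endpoint."""
    per_feature: dict[str, list[Cutoff]] = {}
    for j, slot, q in sorted(selected):
        f = ladder.feature_ids[j]
        per_feature.setdefault(f, []).append(
            Cutoff(float(ladder.values[j][slot]), slot, q))
    return CutoffSet(per_feature)


def adid_discretize(dataset: ExpressionDataset, s_fraction: float = 0.2,
                    tie_policy: str = "lexicographic", refine: bool = True,
                    s: int | None = None) -> CutoffSet:
    """Greedy incremental cutoff selection with redundancy pruning.

    At each step the slot separating the largest number of still-unfulfilled
    constraint units is added (quality measure = count of active constraints
    whose eligible set contains the slot); ties go to the lowest feature
    index then lowest slot (``tie_policy="lexicographic"``) or the highest
    (``"reverse"``).  A final pass removes any cutoff whose deletion leaves
    every constraint fulfilled, so the selection is inclusion-minimal.
    With ``refine=True`` cutoffs are moved to their slot midpoints, which
    leaves all training bins unchanged.
    """
    if tie_policy not in ("lexicographic", "reverse"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    ladder = build_ladder(dataset)
    cons = build_constraints(dataset, ladder, s_fraction=s_fraction, s=s)
    if cons.n_pairs == 0:
        raise ValueError("classes not separable: no satisfiable constraints")

    offsets = _slot_offsets(ladder)
    total_slots = int(offsets[-1])
    # global slot ids: feature j slots occupy [offsets[j], offsets[j+1])
    glo = cons.lo + offsets[:-1][None, :]
    ghi = cons.hi + offsets[:-1][None, :]
    demand = cons.demand.copy()
    selected_mask = np.zeros(total_slots, dtype=bool)
    selected: list[tuple[int, int, float]] = []
    cover_masks: list[np.ndarray] = []  # per selected slot: which pairs it covers

    while (demand > 0).any():
        active = demand > 0
        diff = np.zeros(total_slots + 1, dtype=np.int64)
        np.add.at(diff, glo[active].ravel(), 1)
        np.add.at(diff, ghi[active].ravel(), -1)
        quality = np.cumsum(diff[:-1])
        quality[selected_mask] = -1
        if tie_policy == "lexicographic":
            g = int(np.argmax(quality))
        else:
            g = total_slots - 1 - int(np.argmax(quality[::-1]))
        q = int(quality[g])
        if q <= 0:  # cannot happen for satisfiable constraints; safety stop
            raise RuntimeError("greedy stalled with unfulfilled constraints")
        selected_mask[g] = True
        j = int(np.searchsorted(offsets, g, side="right")) - 1
        selected.append((j, g - int(offsets[j]), float(q)))
        covers = (glo[:, j] <= g) & (g < ghi[:, j])
        cover_masks.append(covers)
        demand[covers] -= 1

    # redundancy pass: drop cutoffs not needed to keep every pair at its
    # required multiplicity, scanning in reverse selection order
    count = np.zeros(cons.n_pairs, dtype=np.int64)
    for m in cover_masks:
        count += m
    keep = [True] * len(selected)
    for i in range(len(selected) - 1, -1, -1):
        m = cover_masks[i]
        if np.all(count[m] - 1 >= cons.demand[m]):
            count -= m
            keep[i] = False
    final = [sel for sel, k in zip(selected, keep) if k]

    cs = _selection_to_cutoffset(final, ladder)
    return refine_cutoffs(cs, ladder) if refine else cs


def refine_cutoffs(cutoffset: CutoffSet, ladder: ValueLadder) -> CutoffSet:
    """Place every cutoff at the midpoint of its slot interval.

    The midpoint stays strictly inside the slot, so the discretized bin of
    every training sample is unchanged.
    """
    out: dict[str, list[Cutoff]] = {}
    for f, cl in cutoffset.cutoffs.items():
        j = ladder.feature_ids.index(f)
        out[f] = [Cutoff(ladder.slot_midpoint(j, c.slot), c.slot, c.quality)
                  for c in cl]
    return CutoffSet(out)


def apply_cutoffs(dataset: ExpressionDataset, cutoffset: CutoffSet) -> np.ndarray:
    """Discretize: bin index = number of cutoffs strictly below the value.

    Left-closed convention: x <= gamma maps to the bin below gamma.
    Features without cutoffs yield bin 0 everywhere.  Returns an (n, d)
    integer matrix aligned with ``dataset.feature_ids``.
    """
    missing = [f for f in cutoffset.cutoffs if f not in dataset.feature_ids]
    if missing:
        raise KeyError(f"cutoff features missing from dataset: {missing}")
    bins = np.zeros((dataset.n, dataset.d), dtype=np.int32)
    for f, cl in cutoffset.cutoffs.items():
        j = dataset.feature_index(f)
        gammas = np.array([c.value for c in cl])
        # value <= gamma -> lower bin, so count cutoffs strictly below x
        bins[:, j] = np.searchsorted(gammas, dataset.values[:, j], side="left")
    return bins


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_min_cutoffs(dataset: ExpressionDataset, s: int = 1,
                            max_total_slots: int = 20,
                            ) -> tuple[int, CutoffSet]:
    """Exact minimum-cutoff solution by exhaustive subset search.

    Solves the same s-reinforced covering problem as the greedy solver,
    returning the optimal count and the lexicographically first optimal
    selection.  Refuses instances with more than ``max_total_slots``
    candidate slots.
    """
    ladder = build_ladder(dataset)
    cons = build_constraints(dataset, ladder, s=s)
    offsets = _slot_offsets(ladder)
    total = int(offsets[-1])
    if total > max_total_slots:
        raise ValueError(f"instance too large for exhaustive search "
                         f"({total} slots > {max_total_slots})")
    glo = cons.lo + offsets[:-1][None, :]
    ghi = cons.hi + offsets[:-1][None, :]
    # membership matrix: pair x slot
    member = np.zeros((cons.n_pairs, total), dtype=bool)
    for g in range(total):
        j = int(np.searchsorted(offsets, g, side="right")) - 1
        member[:, g] = (glo[:, j] <= g) & (g < ghi[:, j])
    for k in range(0, total + 1):
        for combo in itertools.combinations(range(total), k):
            cover = member[:, combo].sum(axis=1) if combo else np.zeros(cons.n_pairs)
            if np.all(cover >= cons.demand):
                sel = []
                for g in combo:
                    j = int(np.searchsorted(offsets, g, side="right")) - 1
                    sel.append((j, g - int(offsets[j]), None))
                return k, _selection_to_cutoffset(sel, ladder)
    raise RuntimeError("unreachable: full slot set always covers")


def fulfills_constraints(cutoffset: CutoffSet, dataset: ExpressionDataset,
                         s: int | None = None, s_fraction: float = 0.2) -> bool:
    """Check whether a cutoff selection meets every separation constraint."""
    ladder = build_ladder(dataset)
    cons = build_constraints(dataset, ladder, s=s, s_fraction=s_fraction)
    count = np.zeros(cons.n_pairs, dtype=np.int64)
    for f, cl in cutoffset.cutoffs.items():
        j = ladder.feature_ids.index(f)
        for c in cl:
            count += (cons.lo[:, j] <= c.slot) & (c.slot < cons.hi[:, j])
    return bool(np.all(count >= cons.demand))


# ---------------------------------------------------------------------------
# single-cutoff baselines

def equal_frequency_cutoff(values) -> float:
    """Single cutoff at the median, snapped to the nearest slot midpoint."""
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    if len(distinct) < 2:
        raise ValueError("equal-frequency cutoff needs >= 2 distinct values")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    med = float(np.median(values))
    return float(mids[np.argmin(np.abs(mids - med))])


def roc_youden_cutoff(values, labels, positive_label: str | None = None,
                      ) -> tuple[float, str, float]:
    """Single cutoff maximizing the Youden index J = sens + spec - 1.

    Scans every slot midpoint in both orientations ("high" = values above
    the cutoff called positive, "low" = values at or below).  Ties break to
    the lowest cutoff, then to the "high" orientation.  Returns
    ``(cutoff, direction, J)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(y) for y in labels])
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("ROC/Youden cutoff needs exactly two classes present")
    if positive_label is None:
        positive_label = classes[0]
    pos = labels == positive_label
    if pos.all() or not pos.any():
        raise ValueError("one class absent")
    distinct = np.unique(values)
    if len(distinct) < 2:
        raise ValueError("needs >= 2 distinct values")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    best = None
    for m in mids:
        above = values > m
        for direction, call_pos in (("high", above), ("low", ~above)):
            sens = (call_pos & pos).sum() / n_pos
            spec = (~call_pos & ~pos).sum() / n_neg
            j = sens + spec - 1.0
            key = (-j, m, direction != "high")
            if best is None or key < best[0]:
                best = (key, float(m), direction, float(j))
    _, cutoff, direction, j = best
    return cutoff, direction, j
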