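# Methods

## Problem setting

`rulecut` targets two-class (extensible to q-class) outcome prediction from
continuous expression matrices on a MAS5-like intensity scale, where the
deliverable is a small set of intelligible threshold rules rather than a
black-box score. The pipeline has four stages — supervised discretization,
rule induction, rule statistics, and conflict-resolving prediction — plus a
univariate survival cross-check and a synthetic cohort generator used
throughout the test suite.

## Supervised discretization

The discretizer solves a minimum-cutoff covering problem: select the fewest
slots (intervals between consecutive distinct observed values of a feature)
such that every cross-class sample pair is separated by at least *s* selected
slots, counted across all features. A slot separates a pair when any cutoff
inside it lies strictly between the pair's two values on that feature; pairs
with identical feature vectors admit no separating slot and are dropped with
a warning (the program is otherwise infeasible). The multiplicity is
*s* = max(1, ⌈s_fraction · d⌉) with s_fraction = 0.2 by default; a pair's
requirement is capped at its number of eligible slots.

The greedy solver scores each unselected slot by the number of active
constraint units it would newly cover and adds the best slot per iteration
(ties: lowest feature index, then lowest slot; a `reverse` tie policy exists
for sensitivity checks). Because a constraint with remaining demand always
retains at least that many unselected eligible slots, the loop terminates
with all constraints fulfilled. A redundancy pass then removes, in reverse
selection order, any cutoff whose deletion leaves every constraint fulfilled,
so the output is inclusion-minimal. An exhaustive solver
(`brute_force_min_cutoffs`, refusing instances above 20 slots) provides the
optimality oracle for tests: greedy count ≥ optimum always, with equality
whenever a single cutoff suffices.

Cutoffs are finally refined to their slot midpoints. The midpoint stays
strictly inside the slot, so no training sample changes bin; it also lands on
round values when the data are integer-granular (a slot between 720 and 722
refines to 721). Binning is left-closed: x ≤ γ falls below the cutoff, so a
dichotomized feature yields exactly the `≤ γ` / `> γ` condition pair.

Two univariate baselines are included: the equal-frequency single cutoff
(median, snapped to the nearest slot midpoint) and the ROC cutoff maximizing
the Youden index J = sensitivity + specificity − 1 over slot midpoints and
both orientations (ties: lowest cutoff, then the high orientation).

## Rule induction

Induction runs on the discretized matrix and follows an aggregative covering
policy. For each class, until every class example is covered: seed a rule
from the uncovered example whose discretized pattern is most frequent among
the class's uncovered examples (tie: lowest sample index); initialize the
premise with that example's bin conditions over all cutoff-bearing features
(bin 0 → `x ≤ γ₁`, top bin → `x > γ_t`, interior bins → `γ_b < x ≤ γ_{b+1}`);
then repeatedly delete the condition whose removal gains the most covering
while the rule's training error stays within the budget E_max (ties: lowest
relevance of the deleted condition, then lowest feature index), stopping when
no deletion fits the budget or one condition remains. Rules may overlap. A
final optional pass (default on) removes rules whose condition set strictly
contains a same-class rule's conditions without covering more, and exact
duplicates. Every training example ends up covered by at least one rule of
its own class; after the discretizer has run, cross-class patterns are
distinct, so seeds start at zero error and every emitted rule respects E_max.

E_max is the fraction of non-class examples a rule may cover. It is selected
by repeated stratified k-fold cross-validation over a grid (default 0–30% in
5% steps, 10 folds, 10 repeats, seed 42): each fold re-runs discretization
and induction on its training part and scores accuracy on the held-out part;
the grid value with the best mean accuracy wins, ties to the smaller value.
CV experiments in the test suite run at reduced sizes (e.g. n = 150, d = 15,
5 folds, grid {0, 0.1, 0.25}), which is where the signature effect — label
noise favoring a positive error budget — is already visible.

An exhaustive enumerator over all ≤ k-condition rules is the induction
oracle on small instances.

## Rule statistics

Confusion counts classify training examples by premise satisfaction ×
class membership; covering, error and precision are the three ratios, with
`None` marking a zero denominator rather than a silent 0. Significance is a
one-sided Fisher exact test (hypergeometric upper tail for enrichment of the
target class among premise-satisfying samples; rules are directional claims —
a two-sided variant is available via flag), significant at p < 0.05 with no
multiple-testing correction across rules.

Condition relevance is R(c) = (E(r′) − E(r)) · C(r) with r′ the rule minus
the condition; for single-condition rules r′ is the always-true premise,
whose error is computed, not assumed. Per-class, per-feature relevance
combines the class's conditions on the feature: unsigned
R_v = 1 − Π(1 − R(c)); signed R_v = Π_neg(1 − R) − Π_pos(1 − R), where ≤/<
conditions contribute to the negative product and >/≥ to the positive one
(a range condition carries both bounds and enters both products; membership
conditions count as positive). A feature used in one direction only thus gets
signed R_v = ±unsigned R_v, and features absent from a class's rules score 0.
Features are ranked by the maximum |signed R_v| across classes (ties by
feature id; all-zero features keep input order).

## Prediction and weighting

For an instance x, let Q be the rules whose premise x satisfies. One matched
class → assigned directly (weights never apply). Conflicting classes →
partition Q into Q_i; each feature j gets consistency t_ij = max R(c) over
conditions on j among Q_i's rules, and the class maximizing w_i · Σ_j t_ij is
assigned (ties: larger unweighted sum, then vocabulary order). Empty Q →
retry allowing 1, then 2, … violated conditions up to the longest premise;
if still empty, fall back to the majority training class with a flag. The
default weights are all ones; the preset sweep (1:1, 26:74, 1:1000, 1000:1)
covers the inverse-proportion and extreme-bias configurations. Weights touch
only conflicted (or fallback-free relaxed-conflict) samples, which is why
extreme weights saturate: once every conflict is decided by sign, the ratio
no longer matters. A covering-based conflict resolver (t from rule covering
instead of condition relevance) is available behind a flag for comparison.

Cohort metrics treat good outcome as the positive class: accuracy, recall,
precision, specificity and NPV from the pooled confusion counts.

## Kaplan–Meier cutoff scan

`scan_best_cutoff` evaluates every slot midpoint of a feature, splits the
cohort into low/high expression groups (both at least `min_group_size`,
default 5), and keeps the cutoff maximizing the two-group log-rank
chi-square (ties: lowest cutoff). The per-cutoff statistics are computed for
all splits at once by prefix sums over the expression order, using the
standard tie-corrected hypergeometric variance; the result at the chosen
cutoff is identical to the pairwise log-rank test, which the suite verifies.
The worse direction is the expression side whose product-limit curve is
lower at the last event time (tie: restricted mean, then "high").
`compare_with_cutoffs` reports, per single-cutoff feature, the scan cutoff
next to the supervised cutoff and their relative difference — a concordance
table that is reported, never asserted against a bound.

The scanned p-value is **not** adjusted for the maximization over cutoffs.
Selecting the maximal statistic over ~n correlated splits inflates the
nominal size badly (roughly half of pure-noise features reach p < 0.05 at
n = 100 in our null simulations, in line with the literature on minimum-p
cutpoint selection), and the scan's argmax localizes the true change point
only to within a few samples rather than to the exact slot. Treat the scan
as a descriptive cross-check of cutoff location and direction, not as a
calibrated test.

## Synthetic cohorts

The generator emulates the study design the classifier is meant for: n = 182
patients (defaults mirror a 109/73 train/test cohort), d = 62 probe sets of
which 11 informative, class prior 74% good / 26% poor. A planted rule set
(auto-generated — every informative feature in at least one rule, good-class
rules using ≤ and poor-class > conditions — or supplied, e.g. the packaged
9-rule classifier) defines thresholds on the informative features. Sampling
is by latent class: the class is drawn from the prior; a low/high side
pattern is drawn among the patterns the planted rules classify as that class,
weighted so each feature shows its class-typical side with probability
`coherence` (default 0.9; 1.0 makes side patterns deterministic — the fully
"noiseless" regime used for parameter-recovery experiments); expression is
then drawn from two right-skewed log-normal components on either side of the
threshold, `value = θ · exp(±(0.05 + |N(0, noise_scale)|))`, leaving a
genuine gap at θ, while uninformative features are class-independent
log-normal noise around 100. Labels are, by construction, exactly what the
planted rules predict; symmetric label flipping at `flip_rate` then emulates
annotation noise. Survival is exponential with per-class hazards (defaults
0.03/yr good, 0.35/yr poor, separating the classes at the 5-year endpoint), a
`censor_rate` fraction lost to follow-up uniformly before their event, and
administrative censoring at the 10-year horizon. Everything is deterministic
per seed.

What the generator does **not** emulate: batch/institute effects, probe-level
noise models, correlated noise features, and non-threshold (dose-dependent)
expression–outcome relationships. Passing tests therefore demonstrate
correctness of the machinery on threshold-structured data, not clinical
performance on real cohorts.

## Packaged fixture

The NB-hypo-II rule set ships as data: 9 rules (6 good, 3 poor, at most two
conditions each) over 11 probe sets with the published covering/error, the
published signed per-class probe-set relevance, the Kaplan–Meier vs rule
cutoff comparison (with each probe set's worse-outcome expression side; one
row's direction is recorded as "high" with a note where the source printed a
typo), and the training/test cohort composition. Operator strictness is
preserved exactly as printed — the same feature appears with `< 326` in one
rule and `≤ 326` in another — and matching honors it.

## Numerical and design choices

- Greedy quality measure: count of newly covered constraint units — the
  direct covering-structure surrogate for the integer program's objective.
- s rounding: ⌈0.2 d⌉ floored at 1; the multiplicity counts cutoffs across
  features (a pair separated four times on one feature satisfies s = 4).
- Error-budget comparisons use a 1e-12 tolerance; monotonicity assertions a
  1e-9 slack.
- Undefined ratios surface as `None`, never 0, so degenerate rules cannot
  masquerade as perfect.
- All RNG flows through `numpy.random.default_rng(seed)`; seeds are mandatory
  in the cohort spec and recorded in every CLI artifact.
- JSON schema for rule sets and cutoffs is versioned (`schema_version: 1`).

## Known limitations

- The greedy discretizer is near-optimal, not optimal; the suite only
  guarantees the oracle bound and single-cutoff equality.
- With label noise the separation constraints force cutoffs onto noise
  features (flipped samples must still be separated), which is precisely why
  a zero error budget overfits and cross-validation picks E_max > 0.
- The scan's unadjusted p-value and slot-exact localization limits are
  described above; direction and approximate location are the reliable
  outputs.
- Rule induction's seed-and-delete search is deterministic but heuristic; the
  exhaustive oracle covers only small instances.
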