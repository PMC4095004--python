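"""Inspect the packaged NB-hypo-II outcome classifier.

Loads the 9-rule neuroblastoma rule set, prints each rule with its
published covering and error, and ranks the probe sets by signed
relevance.  Covering sums above 100% per class show that the rules
overlap: one patient can satisfy several rules of the same outcome.
"""

import rulecut as rc

rs = rc.load_nb_hypo_ii()
print(f"{len(rs)} rules over {len(rs.features)} probe sets\n")
for r in rs:
    print(f"  rule {r.rule_id}: {r.describe():58s} "
          f"covering {r.stats.covering:.0%}  error {r.stats.error:.1%}")

for cls in rs.classes:
    total = 100 * sum(r.stats.covering for r in rs.group(cls))
    print(f"\nsummed covering, {cls} rules: {total:.0f}% "
          f"(> 100% means overlapping rules)")

print("\nprobe sets by relevance (sign: - low / + high expression "
      "associated with the class):")
for f in rc.rank_features(rs.relevance):
    g = rs.relevance.signed["Good"][f]
    p = rs.relevance.signed["Poor"][f]
    print(f"  {f:14s} good {g:+.2f}   poor {p:+.2f}")
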