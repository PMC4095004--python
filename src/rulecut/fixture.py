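"""Packaged NB-hypo-II rule set.

The 9-rule neuroblastoma outcome classifier over 11 hypoxia-signature probe
sets, with the published per-rule covering/error, per-class signed probe-set
relevance, Kaplan-Meier cutoff comparison and training/test cohort
composition attached as metadata.  Thresholds are on the MAS5 intensity
scale; the published mixture of strict and non-strict operators is
preserved verbatim (rule 1 uses ``226452_at < 326`` while rule 2 uses
``<= 326``), and matching honors that strictness exactly.
"""

from __future__ import annotations

import json
from importlib import resources

from .rules import RuleSet

__all__ = ["load_nb_hypo_ii"]


def load_nb_hypo_ii() -> RuleSet:
    """Load the NB-hypo-II 9-rule classifier fixture.

    Returns a :class:`RuleSet` whose rules carry their published covering,
    error and Fisher significance bound (p < 0.001, stored as 0.001), whose
    relevance table holds the published signed per-class probe-set
    relevance, and whose ``metadata`` records the cohort composition
    (109 training / 73 test patients) and the Kaplan-Meier versus rule
    cutoff comparison, including the "worse outcome" expression direction
    per probe set.
    """
    text = resources.files("rulecut").joinpath("data/nb_hypo_ii.json").read_text()
    return RuleSet.from_dict(json.loads(text))
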