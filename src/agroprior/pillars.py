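"""The four pillar classifications.

Geographic origin and vulnerability are single categorical variables mapped
onto three classes.  Economic benefits and food-security importance each
combine four labelled variables through a weighted decision index

    ID = sum_z S_z * w_z / 4,    S_z in {0..3}, w_z = 1/4

classified by half-open threshold intervals into undetermined / low /
medium / high.  The /4 normalization is the unique simple scaling under
which every homogeneous label combination (all variables at score s) lands
in its namesake interval: all-low -> 0.25, all-medium -> 0.5,
all-high -> 0.75; the published "x 100" is display scale only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from . import vocab
from .config import PillarRules, RunConfig
from .fuzzy_core import UNDETERMINED

__all__ = [
    "GeographicAssignment",
    "VulnerabilityAssignment",
    "PillarResult",
    "classify_geographic",
    "classify_vulnerability",
    "aggregate_decision_index",
    "classify_economic",
    "classify_food_security",
    "classify_subindex",
    "enumerate_rule_table",
]

log = logging.getLogger(__name__)

#: maximum per-variable score; the decision index divides by it so that a
#: homogeneous score-s combination yields ID = s/4
_SCORE_SPAN = 4


@dataclass(frozen=True)
class GeographicAssignment:
    regions: frozenset[str]
    label: str  # local | close | distant | undetermined


@dataclass(frozen=True)
class VulnerabilityAssignment:
    national: Optional[str]
    international: Optional[str]
    merged: str  # threatened | minor_concern | not_evaluated


@dataclass
class PillarResult:
    pillar: str  # geographic | vulnerability | economic | food_security
    label: str
    decision_index: Optional[float] = None
    uncertainty: str = "reliable"  # reliable | GP | PCG
    variable_labels: dict[str, str] = field(default_factory=dict)


def classify_geographic(regions: Iterable[str]) -> GeographicAssignment:
    """Three-class origin from the 26-region world vocabulary.

    Precedence local > close > distant: any region containing or neighbouring
    Colombia decides the label regardless of additional distant regions.
    An empty region set is undetermined (candidate for imputation).
    """
    rset = frozenset(regions)
    unknown = rset - vocab.ALL_REGIONS
    if unknown:
        raise ValueError(
            f"unknown region(s) {sorted(unknown)}; valid vocabulary: "
            f"{sorted(vocab.ALL_REGIONS)}"
        )
    if rset & vocab.LOCAL_REGIONS:
        label = "local"
    elif rset & vocab.CLOSE_REGIONS:
        label = "close"
    elif rset:
        label = "distant"
    else:
        label = UNDETERMINED
    return GeographicAssignment(rset, label)


def classify_vulnerability(
    national: Optional[str], international: Optional[str]
) -> VulnerabilityAssignment:
    """Merge national (5-category) and international (6-category) red-list
    statuses into threatened / minor_concern / not_evaluated.

    The more severe source wins when they disagree.
    """
    for src, valid, name in (
        (national, vocab.NATIONAL_VULNERABILITY, "national"),
        (international, vocab.INTERNATIONAL_VULNERABILITY, "international"),
    ):
        if src is not None and src not in valid:
            raise ValueError(f"unknown {name} vulnerability category {src!r}; "
                             f"valid: {sorted(valid)}")
    present = {s for s in (national, international) if s is not None}
    if present & vocab.THREATENED_SOURCES:
        merged = "threatened"
    elif present & vocab.MINOR_CONCERN_SOURCES:
        merged = "minor_concern"
    else:
        merged = "not_evaluated"
    return VulnerabilityAssignment(national, international, merged)


def aggregate_decision_index(
    labels: Mapping[str, str],
    rules: PillarRules,
    score_override: Optional[Mapping[str, Mapping[str, int]]] = None,
) -> tuple[float, str]:
    """Weighted decision index and its threshold class for one rule base.

    ``labels`` must label exactly the rule variables; unknown labels raise.
    ``score_override`` swaps in alternative per-variable score tables (used
    by the affordability-inversion switch).
    """
    if set(labels) != set(rules.variables):
        raise ValueError(
            f"expected labels for {sorted(rules.variables)}, got {sorted(labels)}"
        )
    raw = 0.0
    for var in rules.variables:
        table = (score_override or {}).get(var) or rules.scores[var]
        lab = labels[var]
        if lab not in table:
            raise ValueError(f"unknown label {lab!r} for variable {var!r}; "
                             f"valid: {sorted(table)}")
        raw += table[lab] * rules.weights[var]
    decision_index = raw / _SCORE_SPAN
    return decision_index, rules.thresholds.classify(decision_index)


def classify_economic(labels: Mapping[str, str], cfg: RunConfig) -> PillarResult:
    """Economic-benefits pillar from the lafay / yield / income / coverage labels."""
    di, cls = aggregate_decision_index(labels, cfg.economic_rules)
    return PillarResult("economic", cls, decision_index=di, variable_labels=dict(labels))


def classify_food_security(labels: Mapping[str, str], cfg: RunConfig) -> PillarResult:
    """Food-security pillar from gov_list / traditional / nutrition / affordability."""
    override = None
    if cfg.invert_affordability:
        override = {"affordability": cfg.affordability_scores()}
        log.info("affordability scores inverted (cheap nutrients -> high score)")
    di, cls = aggregate_decision_index(labels, cfg.food_rules, score_override=override)
    return PillarResult("food_security", cls, decision_index=di,
                        variable_labels=dict(labels))


def classify_subindex(labels: Mapping[str, str], rules: PillarRules) -> tuple[float, str]:
    """Four-nutrient sub-index (nutritional contribution or affordability).

    Combines the per-nutrient labels with the same weighted decision index
    and the economic threshold convention; the resulting class becomes one
    labelled input of the food-security pillar.
    """
    return aggregate_decision_index(labels, rules)


def enumerate_rule_table(rules: PillarRules) -> list[dict]:
    """Every label combination of the rule base with its index and class.

    Row count is the product of the per-variable enumeration label sets
    (256 for the economic pillar, 96 for food security).
    """
    variables = rules.variables
    label_sets = [
        rules.enumeration_labels.get(v) or sorted(rules.scores[v]) for v in variables
    ]
    rows = []
    for combo in itertools.product(*label_sets):
        labels = dict(zip(variables, combo))
        di, cls = aggregate_decision_index(labels, rules)
        rows.append({**labels, "decision_index": di, "output_class": cls})
    return rows
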