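"""Final priority class and crisp 0-100 priority value.

Pillar labels are placed on a common ordinal scale (undetermined 0, low 1,
medium 2, high 3).  The class rule: high priority when at least 3 of the 4
pillars sit at level high; otherwise medium when the geographic origin is at
least medium AND at least 2 of the other three pillars are at least medium;
otherwise low.  The crisp value is the centroid of the activated output
Gaussian (15 / 55 / 90 for crisp single-class activation); an optional
blend mode activates every class Gaussian by its share of pillar support to
produce a continuum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .fuzzy_core import centroid_defuzzify

__all__ = ["ORDINAL_SCALE", "pillar_level", "final_class", "priority_value", "rank_all",
           "PriorityResult"]

#: per-pillar label -> ordinal level
ORDINAL_SCALE: dict[str, dict[str, int]] = {
    "geographic": {"undetermined": 0, "distant": 1, "close": 2, "local": 3},
    "vulnerability": {"not_evaluated": 0, "minor_concern": 1, "threatened": 3},
    "economic": {"undetermined": 0, "low": 1, "medium": 2, "high": 3},
    "food_security": {"undetermined": 0, "low": 1, "medium": 2, "high": 3},
}

PILLARS = ("geographic", "vulnerability", "economic", "food_security")

_TAG_SEVERITY = {"reliable": 0, "GP": 1, "PCG": 2}


def pillar_level(pillar: str, label: str) -> int:
    try:
        return ORDINAL_SCALE[pillar][label]
    except KeyError:
        raise ValueError(f"unknown label {label!r} for pillar {pillar!r}") from None


def final_class(levels: Mapping[str, int]) -> str:
    """Priority class from the four ordinal pillar levels."""
    vals = [levels[p] for p in PILLARS]
    if sum(1 for v in vals if v >= 3) >= 3:
        return "high"
    others = [levels[p] for p in PILLARS if p != "geographic"]
    if levels["geographic"] >= 2 and sum(1 for v in others if v >= 2) >= 2:
        return "medium"
    return "low"


def _output_activations(cls: str, levels: Mapping[str, int], cfg: RunConfig,
                        blend: bool) -> dict:
    sets = {s.label: s.function for s in cfg.sets_for("priority_index")}
    if not blend:
        return {cls: (1.0, sets[cls])}
    # blend: each class Gaussian activated by the share of pillars supporting
    # it (level >= 3 -> high, == 2 -> medium, <= 1 -> low), with the crisp
    # class guaranteed at least half activation so the rule outcome dominates
    n = len(PILLARS)
    share = {
        "high": sum(1 for p in PILLARS if levels[p] >= 3) / n,
        "medium": sum(1 for p in PILLARS if levels[p] == 2) / n,
        "low": sum(1 for p in PILLARS if levels[p] <= 1) / n,
    }
    share[cls] = max(share[cls], 0.5)
    return {k: (g, sets[k]) for k, g in share.items() if g > 0}


def priority_value(cls: str, cfg: RunConfig, levels: Mapping[str, int] | None = None,
                   blend: bool = False) -> float:
    """Centroid of the activated prioritizing-index Gaussian(s)."""
    if blend and levels is None:
        raise ValueError("blend mode needs the pillar levels")
    acts = _output_activations(cls, levels or {}, cfg, blend)
    return centroid_defuzzify(acts, cfg.universe_spec())


@dataclass(frozen=True)
class PriorityResult:
    species_id: str
    labels: dict[str, str]
    final_class: str
    priority_value: float
    uncertainty: str  # worst tag across pillars


def rank_all(pillar_table: pd.DataFrame, cfg: RunConfig, blend: bool = False) -> pd.DataFrame:
    """Rank every species by priority value.

    ``pillar_table`` is indexed by species id with columns
    ``geographic_label``, ``vulnerability_label``, ``economic_label``,
    ``food_security_label``, optional decision-index and uncertainty-tag
    columns.  Sort order: priority value desc, then the sum of the two
    decision indices desc, then species id.  Duplicate species ids are a
    data-integrity error.
    """
    if pillar_table.index.duplicated().any():
        dupes = pillar_table.index[pillar_table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate species ids: {dupes}")

    crisp_cache: dict[str, float] = {}
    rows = []
    for sid, row in pillar_table.iterrows():
        levels = {p: pillar_level(p, row[f"{p}_label"]) for p in PILLARS}
        cls = final_class(levels)
        if blend:
            value = priority_value(cls, cfg, levels, blend=True)
        else:
            if cls not in crisp_cache:
                crisp_cache[cls] = priority_value(cls, cfg)
            value = crisp_cache[cls]
        di_sum = 0.0
        for col in ("economic_decision_index", "food_security_decision_index"):
            if col in row.index and pd.notna(row[col]):
                di_sum += float(row[col])
        tags = [row[c] for c in row.index if c.endswith("_uncertainty")]
        worst = max(tags, key=lambda t: _TAG_SEVERITY.get(t, 0), default="reliable")
        rows.append({"species_id": sid, "final_class": cls,
                     "priority_value": round(value, 6),
                     "_di_sum": di_sum, "uncertainty": worst})
    out = pd.DataFrame(rows).set_index("species_id")
    out = out.join(pillar_table)
    out = out.sort_values(by=["priority_value", "_di_sum", "species_id"],
                          ascending=[False, False, True],
                          kind="mergesort")
    return out.drop(columns="_di_sum")
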