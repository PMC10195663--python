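"""Run configuration: every membership parameter, score, weight, threshold
and normalization choice of the index lives here, not in code.

``default_config()`` builds the published parameterisation (the membership
blocks of the source study's parameter table, verbatim); configs round-trip
through YAML for audit and editing.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .fuzzy_core import LabeledFuzzySet, MembershipFunction, Priority, Shape, UniverseSpec

__all__ = ["RunConfig", "MFSpec", "NormalizationSpec", "Thresholds", "PillarRules",
           "default_config", "load_config", "save_config"]


class MFSpec(BaseModel):
    """One labelled membership function of a variable."""

    label: str
    priority: Literal["high", "middle", "low", "undetermined"] = "undetermined"
    shape: Literal["singleton", "trapezoid", "gaussian"]
    a: float = 0.0
    m: float = 0.0
    n: float = 0.0
    b: float = 0.0
    mu: float = 0.0
    sigma: float = 1.0
    sd_singleton: float = 0.001

    def to_set(self) -> LabeledFuzzySet:
        return LabeledFuzzySet(
            label=self.label,
            priority=Priority(self.priority),
            function=MembershipFunction(
                shape=Shape(self.shape), a=self.a, m=self.m, n=self.n, b=self.b,
                mu=self.mu, sigma=self.sigma, sd_singleton=self.sd_singleton,
            ),
        )


class NormalizationSpec(BaseModel):
    """How a raw indicator is brought onto the [0, 100] universe."""

    method: Literal["none", "range_1_100", "log_range_1_100"] = "none"
    per_fao_group: bool = False
    #: fixed source window (lo, hi); None -> use the observed min/max
    domain: Optional[tuple[float, float]] = None
    clip_negative_to_zero: bool = False

    @model_validator(mode="after")
    def _check_domain(self) -> "NormalizationSpec":
        if self.domain is not None and not self.domain[0] < self.domain[1]:
            raise ValueError("normalization domain requires lo < hi")
        return self


class Thresholds(BaseModel):
    """Half-open decision-index class intervals on [0, 1].

    [0, low) -> undetermined, [low, medium) -> low, [medium, high) -> medium,
    [high, 1] -> high.
    """

    low: float = 0.25
    medium: float = 0.46
    high: float = 0.65

    @model_validator(mode="after")
    def _ordered(self) -> "Thresholds":
        if not 0 < self.low < self.medium < self.high <= 1:
            raise ValueError("thresholds must satisfy 0 < low < medium < high <= 1")
        return self

    def classify(self, decision_index: float) -> str:
        if decision_index < self.low:
            return "undetermined"
        if decision_index < self.medium:
            return "low"
        if decision_index < self.high:
            return "medium"
        return "high"


class PillarRules(BaseModel):
    """Weighted decision-index rule base for one pillar (or sub-index).

    ``scores`` maps variable -> label -> ordinal score S_z in {0..3};
    ``weights`` maps variable -> w_z with sum 1; ``enumeration_labels`` lists,
    per variable, the labels counted in the published rule-table cardinality.
    """

    variables: list[str]
    scores: dict[str, dict[str, int]]
    weights: dict[str, float]
    thresholds: Thresholds = Field(default_factory=Thresholds)
    enumeration_labels: dict[str, list[str]] = Field(default_factory=dict)
    output_variable: str = ""

    @model_validator(mode="after")
    def _consistent(self) -> "PillarRules":
        if set(self.variables) != set(self.weights):
            raise ValueError("weights must cover exactly the rule variables")
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights.values())}")
        for v in self.variables:
            if v not in self.scores:
                raise ValueError(f"no scores for variable {v!r}")
        for v, labels in self.enumeration_labels.items():
            missing = [l for l in labels if l not in self.scores[v]]
            if missing:
                raise ValueError(f"enumeration labels {missing} of {v!r} lack scores")
        return self


class GeneratorDefaults(BaseModel):
    """Synthetic-data defaults (see synthetic_data module)."""

    missingness_economic: float = 0.62
    missingness_food: float = 0.73
    fraction_ncb: float = 70 / 345


class RunConfig(BaseModel):
    universe: dict = Field(default_factory=lambda: {"lower": 0.0, "upper": 100.0,
                                                    "resolution": 0.01})
    membership: dict[str, list[MFSpec]]
    economic_rules: PillarRules
    food_rules: PillarRules
    nutrition_rules: PillarRules
    affordability_rules: PillarRules
    total_municipalities: int = 1122
    daily_targets: dict[str, float] = Field(
        default_factory=lambda: {"ca": 1000.0, "fe": 14.0, "zn": 10.0, "energy": 1500.0}
    )
    normalization: dict[str, NormalizationSpec] = Field(default_factory=dict)
    yield_years: tuple[int, int] = (2007, 2017)
    trade_years: tuple[int, int] = (2007, 2017)
    income_year: Literal["latest"] | int = "latest"
    invert_affordability: bool = False
    #: per-species geographic label overrides (species id -> label)
    geographic_overrides: dict[str, str] = Field(default_factory=dict)
    #: crop group -> list of genera it bundles (gene-pool membership beyond genus)
    crop_groups: dict[str, list[str]] = Field(default_factory=dict)
    generator: GeneratorDefaults = Field(default_factory=GeneratorDefaults)

    @field_validator("total_municipalities")
    @classmethod
    def _tm_positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("total_municipalities must be positive")
        return v

    @model_validator(mode="after")
    def _membership_complete(self) -> "RunConfig":
        required = {
            "geographic", "vulnerability", "lafay", "yield", "income", "coverage",
            "economic_output", "gov_list", "traditional", "nutrition",
            "affordability", "food_output", "priority_index",
        }
        missing = required - set(self.membership)
        if missing:
            raise ValueError(f"membership parameter blocks missing: {sorted(missing)}")
        return self

    # -- convenience accessors -------------------------------------------------

    def universe_spec(self) -> UniverseSpec:
        return UniverseSpec(**self.universe)

    def sets_for(self, variable: str) -> list[LabeledFuzzySet]:
        return [s.to_set() for s in self.membership[variable]]

    def affordability_scores(self) -> dict[str, int]:
        """Label scores for the affordability variable of the food pillar,
        honouring the inversion switch (cheap nutrients -> high priority)."""
        base = dict(self.food_rules.scores["affordability"])
        if self.invert_affordability:
            base["low"], base["high"] = base["high"], base["low"]
        return base


# ---------------------------------------------------------------------------
# Default parameterisation
# ---------------------------------------------------------------------------

def _s(label: str, priority: str, a: float) -> dict:
    return {"label": label, "priority": priority, "shape": "singleton", "a": a}


def _t(label: str, priority: str, a: float, m: float, n: float, b: float) -> dict:
    return {"label": label, "priority": priority, "shape": "trapezoid",
            "a": a, "m": m, "n": n, "b": b}


def _g(label: str, priority: str, mu: float, sigma: float) -> dict:
    return {"label": label, "priority": priority, "shape": "gaussian",
            "mu": mu, "sigma": sigma}


#: the published membership-parameter table, verbatim
DEFAULT_MEMBERSHIP: dict[str, list[dict]] = {
    "geographic": [
        _s("distant", "low", 0),
        _s("close", "middle", 45),
        _s("local", "high", 70),
    ],
    "vulnerability": [
        _s("not_evaluated", "undetermined", 0),
        _s("minor_concern", "low", 30),
        _s("threatened", "high", 70),
    ],
    "lafay": [
        _s("undetermined", "undetermined", 0),
        _t("low", "low", 1, 5.2, 10.4, 17.68),
        _t("medium", "middle", 10.4, 20.8, 20.8, 31.12),
        _t("high", "high", 20.8, 31.2, 100, 100),
    ],
    "yield": [
        _s("undetermined", "undetermined", 0),
        _t("low", "low", 4.9, 5, 28.2, 37.6),
        _t("medium", "middle", 28.2, 37.6, 54, 65.2),
        _t("high", "high", 54, 65.2, 100, 100),
    ],
    "income": [
        _s("undetermined", "undetermined", 0),
        _t("low", "low", 4.9, 5, 28.2, 37.6),
        _t("medium", "middle", 28.2, 37.6, 54, 65.2),
        _t("high", "high", 54, 65.2, 105, 110),
    ],
    "coverage": [
        _s("undetermined", "undetermined", 0),
        _t("narrow", "low", 0.99, 1, 15, 30),
        _t("medium", "middle", 20, 25, 50, 60),
        _t("large", "high", 55, 60, 101, 105),
    ],
    "economic_output": [
        _t("undetermined", "undetermined", 0, 0.01, 9.9, 10),
        _t("low", "low", 10, 25, 30, 45),
        _t("medium", "middle", 30, 45, 50, 65),
        _t("high", "high", 50, 65, 70, 85),
    ],
    "gov_list": [
        _s("not_included", "low", 20),
        _s("included", "high", 60),
    ],
    "traditional": [
        _s("undetermined", "undetermined", 0),
        _t("narrow", "low", 0.11, 1, 1.1, 1.25),
        _t("medium", "middle", 1.05, 1.1, 1.15, 1.35),
        _t("large", "high", 1.35, 19, 100, 100),
    ],
    "nutrition": [
        _t("undetermined", "undetermined", 0, 0.01, 9.99, 10),
        _t("low", "low", 10, 26, 30, 45),
        _t("medium", "middle", 30, 45, 50, 65),
        _t("high", "high", 50, 65, 100, 100),
    ],
    "affordability": [
        _t("undetermined", "undetermined", 0, 0.01, 9.99, 10),
        _t("low", "high", 10, 26, 30, 45),
        _t("medium", "middle", 30, 45, 50, 65),
        _t("high", "low", 50, 65, 100, 100),
    ],
    "food_output": [
        _t("undetermined", "undetermined", 0, 0.01, 9.99, 10),
        _t("low", "low", 10, 25, 30, 45),
        _t("medium", "middle", 30, 45, 50, 65),
        _t("high", "high", 50, 65, 70, 85),
    ],
    "priority_index": [
        _g("low", "low", 15, 5),
        _g("medium", "middle", 55, 5),
        _g("high", "high", 90, 5),
    ],
}

_FOUR_LEVEL = {"undetermined": 0, "low": 1, "medium": 2, "high": 3}


def default_config() -> RunConfig:
    """The published parameterisation of the index."""
    econ = PillarRules(
        variables=["lafay", "yield", "income", "coverage"],
        scores={
            "lafay": dict(_FOUR_LEVEL),
            "yield": dict(_FOUR_LEVEL),
            "income": dict(_FOUR_LEVEL),
            "coverage": {"undetermined": 0, "narrow": 1, "medium": 2, "large": 3},
        },
        weights={v: 0.25 for v in ("lafay", "yield", "income", "coverage")},
        thresholds=Thresholds(low=0.25, medium=0.46, high=0.65),
        enumeration_labels={
            "lafay": ["undetermined", "low", "medium", "high"],
            "yield": ["undetermined", "low", "medium", "high"],
            "income": ["undetermined", "low", "medium", "high"],
            "coverage": ["undetermined", "narrow", "medium", "large"],
        },
        output_variable="economic_output",
    )
    food = PillarRules(
        variables=["gov_list", "traditional", "nutrition", "affordability"],
        scores={
            "gov_list": {"not_included": 0, "included": 3},
            "traditional": {"undetermined": 0, "narrow": 0, "medium": 1, "large": 3},
            # the published scores name only 0/1/3 levels; "medium" nutrition and
            # affordability carry 2 by analogy with the economic scale
            "nutrition": dict(_FOUR_LEVEL),
            "affordability": dict(_FOUR_LEVEL),
        },
        weights={v: 0.25 for v in ("gov_list", "traditional", "nutrition", "affordability")},
        thresholds=Thresholds(low=0.25, medium=0.45, high=0.65),
        enumeration_labels={
            "gov_list": ["not_included", "included"],
            "traditional": ["narrow", "medium", "large"],
            "nutrition": ["undetermined", "low", "medium", "high"],
            "affordability": ["undetermined", "low", "medium", "high"],
        },
        output_variable="food_output",
    )
    nutrients = ["ca", "fe", "zn", "energy"]
    sub = dict(
        variables=nutrients,
        scores={n: dict(_FOUR_LEVEL) for n in nutrients},
        weights={n: 0.25 for n in nutrients},
        thresholds=Thresholds(low=0.25, medium=0.46, high=0.65),
        enumeration_labels={n: ["undetermined", "low", "medium", "high"] for n in nutrients},
    )
    return RunConfig(
        membership={k: [MFSpec(**d) for d in v] for k, v in DEFAULT_MEMBERSHIP.items()},
        economic_rules=econ,
        food_rules=food,
        nutrition_rules=PillarRules(**sub, output_variable="nutrition"),
        affordability_rules=PillarRules(**sub, output_variable="affordability"),
        normalization={
            # income spans orders of magnitude: log first, then range to [1,100]
            "income": NormalizationSpec(method="log_range_1_100"),
            "lafay": NormalizationSpec(method="range_1_100", clip_negative_to_zero=True),
            # yields are comparable only within an FAO food category
            "yield": NormalizationSpec(method="range_1_100", per_fao_group=True),
            "coverage": NormalizationSpec(method="none"),
            "traditional": NormalizationSpec(method="range_1_100", domain=(1.0, 8.0)),
            "nutrition": NormalizationSpec(method="none"),
            "affordability": NormalizationSpec(method="range_1_100"),
        },
    )


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
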