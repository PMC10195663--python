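import pytest

from agroprior.config import PillarRules, Thresholds, default_config
from agroprior.pillars import (aggregate_decision_index, classify_economic,
                               classify_food_security, classify_geographic,
                               classify_subindex, classify_vulnerability,
                               enumerate_rule_table)

CLASS_RANK = {"undetermined": 0, "low": 1, "medium": 2, "high": 3}


class TestGeographic:
    @pytest.mark.parametrize("regions, label", [
        ({"Andes"}, "local"),
        ({"Tropical South America"}, "local"),
        ({"Caribbean"}, "close"),
        ({"Temperate South America"}, "close"),
        ({"Australia"}, "distant"),
        ({"Australia", "Andes"}, "local"),            # local precedence
        ({"Australia", "Caribbean"}, "close"),        # close precedence
        (set(), "undetermined"),
    ])
    def test_labels(self, regions, label):
        assert classify_geographic(regions).label == label

    def test_unknown_region_lists_vocabulary(self):
        with pytest.raises(ValueError, match="Andes"):
            classify_geographic({"Atlantis"})


class TestVulnerability:
    @pytest.mark.parametrize("nat, intl, merged", [
        ("vulnerable", None, "threatened"),
        ("endangered", "least concern", "threatened"),   # severe source wins
        (None, "critically endangered", "threatened"),
        (None, "least concern", "minor_concern"),
        ("near threatened", None, "minor_concern"),
        ("minor concern", None, "minor_concern"),
        ("not evaluated", None, "not_evaluated"),
        (None, None, "not_evaluated"),
    ])
    def test_merge(self, nat, intl, merged):
        assert classify_vulnerability(nat, intl).merged == merged

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="national"):
            classify_vulnerability("extinct", None)


class TestDecisionIndex:
    def test_homogeneous_labels_land_in_namesake_interval(self, cfg):
        # a score-s label on every variable must classify as the level-s class
        # under both threshold conventions
        for rules in (cfg.economic_rules, cfg.nutrition_rules):
            for cls in ("undetermined", "low", "medium", "high"):
                labels = {}
                for v in rules.variables:
                    inv = {s: l for l, s in rules.scores[v].items()}
                    labels[v] = inv[CLASS_RANK[cls]]
                di, got = aggregate_decision_index(labels, rules)
                assert di == pytest.approx(CLASS_RANK[cls] / 4)
                assert got == cls
        # the food thresholds classify the same homogeneous indices identically
        food_thr = cfg.food_rules.thresholds
        assert [food_thr.classify(s / 4) for s in range(4)] == \
            ["undetermined", "low", "medium", "high"]

    def test_three_high_one_missing_is_medium(self, cfg):
        labels = {"lafay": "high", "yield": "high", "income": "high",
                  "coverage": "undetermined"}
        res = classify_economic(labels, cfg)
        assert res.decision_index == pytest.approx(0.5625)
        assert res.label == "medium"

    @pytest.mark.parametrize("labels, di, cls", [
        ({"gov_list": "included", "traditional": "large",
          "nutrition": "high", "affordability": "high"}, 0.75, "high"),
        ({"gov_list": "not_included", "traditional": "narrow",
          "nutrition": "undetermined", "affordability": "undetermined"}, 0.0,
         "undetermined"),
        ({"gov_list": "included", "traditional": "medium",
          "nutrition": "low", "affordability": "low"}, 0.375, "low"),
    ])
    def test_food_security_examples(self, cfg, labels, di, cls):
        res = classify_food_security(labels, cfg)
        assert res.decision_index == pytest.approx(di)
        assert res.label == cls

    def test_unknown_label_rejected(self, cfg):
        with pytest.raises(ValueError, match="unknown label"):
            classify_economic({"lafay": "extreme", "yield": "low",
                               "income": "low", "coverage": "narrow"}, cfg)

    def test_wrong_variable_set_rejected(self, cfg):
        with pytest.raises(ValueError, match="expected labels"):
            aggregate_decision_index({"lafay": "low"}, cfg.economic_rules)

    def test_affordability_inversion_swaps_low_and_high(self, cfg):
        inv = cfg.model_copy(deep=True)
        inv.invert_affordability = True
        labels = {"gov_list": "not_included", "traditional": "narrow",
                  "nutrition": "undetermined", "affordability": "low"}
        assert classify_food_security(labels, cfg).decision_index == pytest.approx(1 / 16)
        assert classify_food_security(labels, inv).decision_index == pytest.approx(3 / 16)

    def test_subindex_uses_economic_thresholds(self, cfg):
        labels = {"ca": "high", "fe": "high", "zn": "high", "energy": "undetermined"}
        di, cls = classify_subindex(labels, cfg.nutrition_rules)
        assert di == pytest.approx(0.5625) and cls == "medium"


class TestRuleTable:
    def test_cardinalities(self, cfg):
        assert len(enumerate_rule_table(cfg.economic_rules)) == 256
        assert len(enumerate_rule_table(cfg.food_rules)) == 96

    def test_single_variable_table(self):
        rules = PillarRules(
            variables=["x"],
            scores={"x": {"undetermined": 0, "low": 1, "medium": 2, "high": 3}},
            weights={"x": 1.0}, thresholds=Thresholds())
        assert len(enumerate_rule_table(rules)) == 4

    @pytest.mark.parametrize("which", ["economic_rules", "food_rules"])
    def test_monotone_in_every_variable(self, cfg, which):
        """Raising one variable's score never lowers the output class."""
        rules = getattr(cfg, which)
        rows = enumerate_rule_table(rules)
        for row in rows:
            for var in rules.variables:
                score = rules.scores[var][row[var]]
                for other, s in rules.scores[var].items():
                    if s <= score or other not in (rules.enumeration_labels[var]):
                        continue
                    bumped = {v: row[v] for v in rules.variables}
                    bumped[var] = other
                    _, cls = aggregate_decision_index(bumped, rules)
                    assert CLASS_RANK[cls] >= CLASS_RANK[row["output_class"]]

    def test_each_row_has_exactly_one_class(self, cfg):
        for row in enumerate_rule_table(cfg.economic_rules):
            assert row["output_class"] in CLASS_RANK
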