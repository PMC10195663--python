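import numpy as np
import pandas as pd
import pytest

from agroprior.imputation import apply_imputation, resolve_donor


def make_species(rows):
    df = pd.DataFrame(rows, columns=["species_id", "group", "genus", "fao_category"])
    return df.set_index("species_id")


SPECIES = make_species([
    # a pepper-like genus with several congeners carrying data
    ("cap_missing", "BGVCOL", "Capsicum", "vegetables and melons"),
    ("cap_rich", "BGVCOL", "Capsicum", "vegetables and melons"),
    ("cap_poor", "BGVCOL", "Capsicum", "vegetables and melons"),
    # a citrus-like recipient with no congener but a shared FAO category
    ("cit_missing", "BGVCOL", "Citrus", "fruits and nuts"),
    ("fruit_donor", "BGVCOL", "Passiflora", "fruits and nuts"),
    # an externally listed species: never imputed
    ("ncb_missing", "NCB", "Coffea", "beverage and spice"),
    # an isolated species with neither congener nor category mate
    ("orphan", "BGVCOL", "Orphanus", "sugar crops"),
])

VALUES = pd.DataFrame(
    {
        "v1": [np.nan, 80.0, 20.0, np.nan, 10.0, np.nan, np.nan],
        "v2": [np.nan, 70.0, np.nan, np.nan, 30.0, np.nan, np.nan],
    },
    index=SPECIES.index,
)
# own decision index: cap_poor is the worst-case congener
OWN_DI = pd.Series([np.nan, 0.75, 0.25, np.nan, 0.5, np.nan, np.nan],
                   index=SPECIES.index)
GENUS_GROUPS = {s: g for s, g in SPECIES["genus"].items()}


def has_data():
    return VALUES.notna().any(axis=1)


class TestResolveDonor:
    def test_gene_pool_preferred_and_worst_case(self):
        res = resolve_donor("cap_missing", "economic", SPECIES, has_data(),
                            OWN_DI, GENUS_GROUPS)
        assert res.path == "GP"
        assert res.donor == "cap_poor"  # lowest decision index among congeners

    def test_pcg_fallback_when_no_congener(self):
        res = resolve_donor("cit_missing", "economic", SPECIES, has_data(),
                            OWN_DI, GENUS_GROUPS)
        assert res.path == "PCG" and res.donor == "fruit_donor"

    def test_ncb_never_imputed(self):
        res = resolve_donor("ncb_missing", "economic", SPECIES, has_data(),
                            OWN_DI, GENUS_GROUPS)
        assert res.path == "none" and res.donor is None

    def test_no_donor_anywhere(self):
        res = resolve_donor("orphan", "economic", SPECIES, has_data(),
                            OWN_DI, GENUS_GROUPS)
        assert res.path == "none"

    def test_species_with_data_is_noop(self):
        res = resolve_donor("cap_rich", "economic", SPECIES, has_data(),
                            OWN_DI, GENUS_GROUPS)
        assert res.path == "none" and res.donor is None

    def test_tie_breaks_lexicographically(self):
        di = OWN_DI.copy()
        di["cap_rich"] = 0.25  # tie with cap_poor
        res = resolve_donor("cap_missing", "economic", SPECIES, has_data(),
                            di, GENUS_GROUPS)
        assert res.donor == "cap_poor"  # "cap_poor" < "cap_rich"

    def test_crop_group_config_extends_gene_pool(self):
        # bundle Citrus with Passiflora into one crop group -> GP, not PCG
        groups = dict(GENUS_GROUPS)
        groups["cit_missing"] = "citrus-group"
        groups["fruit_donor"] = "citrus-group"
        res = resolve_donor("cit_missing", "economic", SPECIES, has_data(),
                            OWN_DI, groups)
        assert res.path == "GP" and res.donor == "fruit_donor"


class TestApplyImputation:
    def test_fills_tags_and_audits(self):
        filled, tags, audit = apply_imputation(VALUES, SPECIES, OWN_DI,
                                               "economic", GENUS_GROUPS)
        assert filled.at["cap_missing", "v1"] == 20.0  # from cap_poor
        assert np.isnan(filled.at["cap_missing", "v2"])  # donor lacks it too
        assert tags["cap_missing"] == "GP"
        assert tags["cit_missing"] == "PCG"
        assert tags["ncb_missing"] == "reliable"
        assert set(audit["recipient"]) == {"cap_missing", "cit_missing"}

    def test_partial_data_is_kept_not_overwritten(self):
        filled, tags, _ = apply_imputation(VALUES, SPECIES, OWN_DI,
                                           "economic", GENUS_GROUPS)
        # cap_poor has v1 but not v2: it is data-bearing, so not a recipient
        assert np.isnan(filled.at["cap_poor", "v2"])
        assert tags["cap_poor"] == "reliable"

    def test_idempotent_on_complete_records(self):
        complete = VALUES.fillna(1.0)
        filled, tags, audit = apply_imputation(complete, SPECIES, OWN_DI,
                                               "economic", GENUS_GROUPS)
        pd.testing.assert_frame_equal(filled, complete)
        assert (tags == "reliable").all() and audit.empty

    def test_tag_accounting_balances(self):
        _, tags, _ = apply_imputation(VALUES, SPECIES, OWN_DI,
                                      "economic", GENUS_GROUPS)
        counts = tags.value_counts()
        assert counts.sum() == len(SPECIES)

    def test_trigger_columns_exclude_presence_only_fields(self):
        vals = VALUES.copy()
        vals["flag"] = 1.0  # present for everyone (like list membership)
        filled, tags, _ = apply_imputation(vals, SPECIES, OWN_DI, "economic",
                                           GENUS_GROUPS,
                                           trigger_columns=["v1", "v2"])
        assert tags["cap_missing"] == "GP"  # still imputed despite the flag
        # without trigger restriction the universal flag blocks everything
        _, tags2, _ = apply_imputation(vals, SPECIES, OWN_DI, "economic",
                                       GENUS_GROUPS)
        assert (tags2 == "reliable").all()
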