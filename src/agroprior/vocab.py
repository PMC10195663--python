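"""Controlled vocabularies: regions of diversity, FAO food categories,
vulnerability categories, and species groups."""

from __future__ import annotations

BGVCOL = "BGVCOL"  # conserved in the national plant germplasm bank
NCB = "NCB"        # government-listed but not conserved in the bank

GROUPS = (BGVCOL, NCB)

#: regions of diversity containing Colombia -> "local" origin
LOCAL_REGIONS = frozenset({"Andes", "Tropical South America"})

#: regions neighbouring the local ones -> "close" origin
CLOSE_REGIONS = frozenset({
    "Caribbean",
    "Central America and Mexico",
    "Temperate South America",
})

#: the remaining 21 regions of the 26-region world vocabulary -> "distant"
DISTANT_REGIONS = frozenset({
    "Australia",
    "Indian Ocean Islands",
    "Central Africa",
    "East Africa",
    "Southern Africa",
    "West Africa",
    "North Africa",
    "North America",
    "Asia",
    "West Asia",
    "South Asia",
    "Southeast Asia",
    "Central Asia",
    "East Asia",
    "Europe",
    "Southeast Europe",
    "Northeast Europe",
    "Southwest Europe",
    "Northwest Europe",
    "South Mediterranean",
    "East Mediterranean",
})

ALL_REGIONS = frozenset(LOCAL_REGIONS | CLOSE_REGIONS | DISTANT_REGIONS)
assert len(ALL_REGIONS) == 26

#: the nine FAO food categories used for stratification and PCG imputation
FAO_CATEGORIES = frozenset({
    "beverage and spice",
    "cereals",
    "fruits and nuts",
    "leguminous",
    "oilseed",
    "other crops",
    "roots and tubers",
    "sugar crops",
    "vegetables and melons",
})

#: national red-list catalogue (five categories)
NATIONAL_VULNERABILITY = frozenset({
    "endangered",
    "vulnerable",
    "near threatened",
    "minor concern",
    "not evaluated",
})

#: international databases (six categories)
INTERNATIONAL_VULNERABILITY = frozenset({
    "critically endangered",
    "endangered",
    "vulnerable",
    "near threatened",
    "least concern",
    "not evaluated",
})

#: any of these, from either source, makes the merged status "threatened"
THREATENED_SOURCES = frozenset({"critically endangered", "endangered", "vulnerable"})

#: any of these (and nothing threatened) makes the merged status "minor_concern"
MINOR_CONCERN_SOURCES = frozenset({"near threatened", "least concern", "minor concern"})
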