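"""Taxonomic donor imputation with uncertainty provenance.

Species conserved in the national germplasm bank (BGVCOL group) with missing
economic, food-security or geographic inputs borrow values from a donor in
the same dataset: first choice a gene-pool (GP) donor sharing the genus or a
configured crop group, fallback a provisional-crop-group (PCG) donor sharing
the FAO food category.  Among eligible donors the worst case in terms of
data is chosen — the donor whose own data yield the lowest decision index
for that pillar — so imputation cannot inflate priority.  Every pillar
result carries a provenance tag: reliable (own data, or nothing to borrow),
GP, or PCG.  Vulnerability is never imputed, and neither is anything for the
externally listed (NCB) species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from . import vocab

__all__ = ["DonorResolution", "resolve_donor", "apply_imputation"]

log = logging.getLogger(__name__)

RELIABLE, GP, PCG = "reliable", "GP", "PCG"


@dataclass(frozen=True)
class DonorResolution:
    recipient: str
    donor: Optional[str]
    path: str  # GP | PCG | none
    pillar: str


def resolve_donor(
    recipient: str,
    pillar: str,
    species: pd.DataFrame,
    has_data: pd.Series,
    own_index: pd.Series,
    crop_group_of: Mapping[str, str],
) -> DonorResolution:
    """Pick the worst-case GP donor, else the worst-case PCG donor, else none.

    ``species`` is indexed by species id with columns ``group``, ``genus``
    and ``fao_category``.  ``has_data`` flags species carrying their own data
    for the pillar; ``own_index`` is the decision index (or ordinal level,
    for the geographic pillar) computed from each donor's own data.  Ties on
    the minimum index break lexicographically on species id.
    """
    rec = species.loc[recipient]
    if rec["group"] != vocab.BGVCOL:
        return DonorResolution(recipient, None, "none", pillar)
    if has_data.get(recipient, False):
        return DonorResolution(recipient, None, "none", pillar)

    pool = species[(species["group"] == vocab.BGVCOL) & (species.index != recipient)]
    pool = pool[has_data.reindex(pool.index, fill_value=False)]

    def worst(candidates: pd.Index) -> Optional[str]:
        if len(candidates) == 0:
            return None
        sub = own_index.reindex(candidates)
        lowest = sub.min()
        return sorted(sub[sub == lowest].index)[0]

    rec_group = crop_group_of.get(recipient, rec["genus"])
    gp = worst(pool.index[[crop_group_of.get(s, g) == rec_group
                           for s, g in pool["genus"].items()]])
    if gp is not None:
        return DonorResolution(recipient, gp, GP, pillar)
    pcg = worst(pool.index[pool["fao_category"] == rec["fao_category"]])
    if pcg is not None:
        return DonorResolution(recipient, pcg, PCG, pillar)
    return DonorResolution(recipient, None, "none", pillar)


def apply_imputation(
    values: pd.DataFrame,
    species: pd.DataFrame,
    own_index: pd.Series,
    pillar: str,
    crop_group_of: Mapping[str, str],
    trigger_columns: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Fill missing pillar variables from resolved donors.

    ``values`` holds one column per pillar variable (NaN = missing) for every
    species.  A species is treated as data-bearing (hence never a recipient,
    always a potential donor) when any of ``trigger_columns`` (default: all
    columns) is present.  Returns the filled copy, a per-species uncertainty
    tag series, and an audit table (recipient, donor, path, variables
    filled).  Original values are never overwritten, and a donor missing a
    variable leaves it missing.  Complete species (and all NCB species) pass
    through untouched with the reliable tag.
    """
    filled = values.copy()
    tags = pd.Series(RELIABLE, index=values.index, name="uncertainty")
    has_data = values[trigger_columns or list(values.columns)].notna().any(axis=1)
    audit_rows: list[dict] = []

    incomplete = values.index[values.isna().any(axis=1)]
    for rec in incomplete:
        res = resolve_donor(rec, pillar, species, has_data, own_index, crop_group_of)
        if res.donor is None:
            continue
        donor_vals = values.loc[res.donor]
        to_fill = [c for c in values.columns
                   if pd.isna(values.at[rec, c]) and pd.notna(donor_vals[c])]
        if not to_fill:
            continue
        for c in to_fill:
            filled.at[rec, c] = donor_vals[c]
        tags.at[rec] = GP if res.path == GP else PCG
        log.info("imputed %s pillar of %s from %s donor %s (%s)",
                 pillar, rec, res.path, res.donor, ", ".join(to_fill))
        audit_rows.append({
            "recipient": rec, "pillar": pillar, "donor": res.donor,
            "path": res.path, "variables_filled": ";".join(to_fill),
        })

    audit = pd.DataFrame(audit_rows,
                         columns=["recipient", "pillar", "donor", "path",
                                  "variables_filled"])
    return filled, tags, audit
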