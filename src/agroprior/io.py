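"""Schema-validated input readers, the end-to-end pipeline, and table writers.

Input directory layout (comma-separated, UTF-8, header row required; the
species registry is mandatory, every other table optional — an absent or
empty table simply leaves its variables missing):

    species.csv          species_id, taxon, group, genus, fao_category
    regions.csv          species_id, region            (one row per region)
    vulnerability.csv    species_id, national, international
    economics.csv        species_id, year, production_t, area_ha,
                         price_usd_per_t, imports_t, exports_t, municipalities
    nutrition.csv        species_id, ca_mg, fe_mg, zn_mg, energy_kcal,
                         consumption_g_day, price_usd_100g
    government_list.csv  species_id, included
    traditional.csv      species_id, regions_count

``run_pipeline`` produces the indicator table, the pillar table, the
imputation audit, the ranked priority list and a summary — deterministically
for identical inputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import indicators as ind
from . import vocab
from .config import NormalizationSpec, RunConfig
from .fuzzy_core import UNDETERMINED, fuzzify
from .imputation import apply_imputation
from .pillars import (classify_economic, classify_food_security, classify_geographic,
                      classify_subindex, classify_vulnerability)
from .ranking import ORDINAL_SCALE, rank_all

__all__ = ["Dataset", "SchemaError", "load_inputs", "run_pipeline", "PipelineOutputs"]

log = logging.getLogger(__name__)

NUTRIENTS = ("ca", "fe", "zn", "energy")

ECON_VARS = ("lafay", "yield", "income", "coverage")


class SchemaError(ValueError):
    """Input validation failed; ``errors`` lists every offending row."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("input validation failed:\n" + "\n".join(errors))


@dataclass
class Dataset:
    species: pd.DataFrame  # indexed by species_id
    regions: pd.DataFrame
    vulnerability: pd.DataFrame
    economics: pd.DataFrame
    nutrition: pd.DataFrame
    government: pd.DataFrame
    traditional: pd.DataFrame
    validation_errors: list[str] = field(default_factory=list)

    def regions_of(self, species_id: str) -> frozenset[str]:
        sub = self.regions[self.regions["species_id"] == species_id]
        return frozenset(sub["region"])


def _read(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        return pd.DataFrame(columns=columns)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError([f"{path.name}: missing required column(s) {missing}"])
    return df


def load_inputs(input_dir: str | Path, strict: bool = True) -> Dataset:
    """Read and validate every input table of a run directory.

    With ``strict`` (default) any validation error raises :class:`SchemaError`
    naming the file, line and valid vocabulary; otherwise errors are collected
    on ``Dataset.validation_errors`` for reporting.
    """
    d = Path(input_dir)
    errors: list[str] = []

    species = _read(d / "species.csv", ["species_id", "group", "genus", "fao_category"])
    if species.empty:
        raise SchemaError([f"{d / 'species.csv'}: species registry is required"])
    dup = species["species_id"][species["species_id"].duplicated()].unique().tolist()
    if dup:
        errors.append(f"species.csv: duplicate species ids {dup}")
    for i, row in species.iterrows():
        line = i + 2  # header + 1-based
        if row["group"] not in vocab.GROUPS:
            errors.append(f"species.csv line {line}: unknown group {row['group']!r}; "
                          f"valid: {sorted(vocab.GROUPS)}")
        if pd.notna(row["fao_category"]) and row["fao_category"] not in vocab.FAO_CATEGORIES:
            errors.append(f"species.csv line {line}: unknown FAO category "
                          f"{row['fao_category']!r}; valid: {sorted(vocab.FAO_CATEGORIES)}")

    regions = _read(d / "regions.csv", ["species_id", "region"])
    for i, row in regions.iterrows():
        if row["region"] not in vocab.ALL_REGIONS:
            errors.append(f"regions.csv line {i + 2}: unknown region {row['region']!r}; "
                          f"valid: {sorted(vocab.ALL_REGIONS)}")

    vulnerability = _read(d / "vulnerability.csv", ["species_id", "national", "international"])
    for i, row in vulnerability.iterrows():
        if pd.notna(row["national"]) and row["national"] not in vocab.NATIONAL_VULNERABILITY:
            errors.append(f"vulnerability.csv line {i + 2}: unknown national category "
                          f"{row['national']!r}; valid: {sorted(vocab.NATIONAL_VULNERABILITY)}")
        if (pd.notna(row["international"])
                and row["international"] not in vocab.INTERNATIONAL_VULNERABILITY):
            errors.append(f"vulnerability.csv line {i + 2}: unknown international category "
                          f"{row['international']!r}; "
                          f"valid: {sorted(vocab.INTERNATIONAL_VULNERABILITY)}")

    economics = _read(d / "economics.csv",
                      ["species_id", "year", "production_t", "area_ha", "price_usd_per_t",
                       "imports_t", "exports_t", "municipalities"])
    nutrition = _read(d / "nutrition.csv",
                      ["species_id", "ca_mg", "fe_mg", "zn_mg", "energy_kcal",
                       "consumption_g_day", "price_usd_100g"])
    government = _read(d / "government_list.csv", ["species_id", "included"])
    traditional = _read(d / "traditional.csv", ["species_id", "regions_count"])

    known = set(species["species_id"])
    for name, df in (("regions", regions), ("vulnerability", vulnerability),
                     ("economics", economics), ("nutrition", nutrition),
                     ("government_list", government), ("traditional", traditional)):
        stray = sorted(set(df["species_id"]) - known)
        if stray:
            errors.append(f"{name}.csv: species ids not in the registry: {stray}")

    if errors and strict:
        raise SchemaError(errors)
    return Dataset(species.set_index("species_id"), regions, vulnerability,
                   economics, nutrition, government, traditional,
                   validation_errors=errors)


# ---------------------------------------------------------------------------
# Indicator computation and normalization
# ---------------------------------------------------------------------------

def compute_indicators(ds: Dataset, cfg: RunConfig) -> pd.DataFrame:
    """One row per species: raw economic and nutritional indicator values."""
    rows = {}
    econ = ds.economics
    nut = ds.nutrition.set_index("species_id") if len(ds.nutrition) else ds.nutrition
    # species absent from the government table have unknown list status (NaN);
    # an explicit 0/1 row records known non-membership/membership
    if len(ds.government):
        gov_flag = {
            r["species_id"]:
                1.0 if str(r["included"]).strip().lower() in {"1", "1.0", "true", "yes"}
                else 0.0
            for _, r in ds.government.iterrows()
        }
    else:
        gov_flag = {}
    trad = (ds.traditional.set_index("species_id")["regions_count"]
            if len(ds.traditional) else pd.Series(dtype=float))

    y0, y1 = cfg.yield_years
    t0, t1 = cfg.trade_years
    for sid in ds.species.index:
        e = econ[econ["species_id"] == sid] if len(econ) else econ
        row: dict[str, float] = {}

        # income: the latest year carrying price, production and area
        inc = math.nan
        if len(e):
            ey = e.dropna(subset=["price_usd_per_t", "production_t", "area_ha"])
            if cfg.income_year != "latest":
                ey = ey[ey["year"] == cfg.income_year]
            if len(ey):
                last = ey.loc[ey["year"].idxmax()]
                inc = ind.income(last["price_usd_per_t"], last["production_t"],
                                 last["area_ha"])
        row["income"] = inc

        # yield: multi-year means inside the configured window
        ew = e[(e["year"] >= y0) & (e["year"] <= y1)] if len(e) else e
        row["yield"] = (ind.crop_yield(ew["production_t"].tolist(),
                                       ew["area_ha"].tolist())
                        if len(ew) else math.nan)

        # lafay: mean trade flows over the trade window
        et = e[(e["year"] >= t0) & (e["year"] <= t1)] if len(e) else e
        et = et.dropna(subset=["production_t", "imports_t", "exports_t"]) if len(et) else et
        if len(et):
            row["lafay"] = ind.lafay(et["production_t"].mean(), et["imports_t"].mean(),
                                     et["exports_t"].mean())
        else:
            row["lafay"] = math.nan

        # coverage: municipality count of the latest year reporting one
        cov = math.nan
        if len(e):
            em = e.dropna(subset=["municipalities"])
            if len(em):
                cov = ind.municipality_coverage(em.loc[em["year"].idxmax(),
                                                       "municipalities"],
                                                cfg.total_municipalities)
        row["coverage"] = cov

        if sid in getattr(nut, "index", []):
            nrow = nut.loc[sid]
            for k, col in zip(NUTRIENTS, ("ca_mg", "fe_mg", "zn_mg", "energy_kcal")):
                row[f"c_{k}"] = ind.nutritional_contribution(
                    nrow["consumption_g_day"], nrow[col], cfg.daily_targets[k])
                row[f"a_{k}"] = ind.nutrient_price_ratio(nrow["price_usd_100g"], nrow[col])
        else:
            for k in NUTRIENTS:
                row[f"c_{k}"] = math.nan
                row[f"a_{k}"] = math.nan

        row["traditional"] = float(trad.get(sid, math.nan))
        row["gov_included"] = gov_flag.get(sid, math.nan)
        rows[sid] = row

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "species_id"
    return out


def _normalize_column(values: pd.Series, spec: NormalizationSpec,
                      groups: Optional[pd.Series] = None) -> pd.Series:
    x = values.astype(float).copy()
    if spec.clip_negative_to_zero:
        x[x < 0] = 0.0
    if spec.method == "none":
        return x
    if spec.method == "log_range_1_100":
        pos = x > 0
        logged = pd.Series(np.nan, index=x.index)
        logged[pos] = np.log10(x[pos])
        out = _range_map(logged, spec.domain)
        out[x.notna() & ~pos] = 1.0  # zero-or-negative collapses to the floor
        return out
    if spec.per_fao_group and groups is not None:
        out = pd.Series(np.nan, index=x.index)
        for _, idx in x.groupby(groups.reindex(x.index)).groups.items():
            out.loc[idx] = _range_map(x.loc[idx], spec.domain)
        return out
    return _range_map(x, spec.domain)


def _range_map(x: pd.Series, domain: Optional[tuple[float, float]]) -> pd.Series:
    if domain is not None:
        lo, hi = domain
        out = 1.0 + 99.0 * (x.clip(lo, hi) - lo) / (hi - lo)
        return out
    return pd.Series(ind.range_normalize(x.tolist()), index=x.index)


def normalize_indicators(raw: pd.DataFrame, species: pd.DataFrame,
                         cfg: RunConfig) -> pd.DataFrame:
    """Append fuzzification-scale columns (``*_fz``) per the config."""
    out = raw.copy()
    fao = species["fao_category"]
    colmap = {
        "income": ["income"], "lafay": ["lafay"], "yield": ["yield"],
        "coverage": ["coverage"], "traditional": ["traditional"],
        "nutrition": [f"c_{k}" for k in NUTRIENTS],
        "affordability": [f"a_{k}" for k in NUTRIENTS],
    }
    for var, cols in colmap.items():
        spec = cfg.normalization.get(var, NormalizationSpec())
        for c in cols:
            out[f"{c}_fz"] = _normalize_column(raw[c], spec, groups=fao)
    return out


# ---------------------------------------------------------------------------
# Fuzzification + pillar classification
# ---------------------------------------------------------------------------

def _label_value(x: float, sets) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return UNDETERMINED
    return fuzzify(x, sets).label


def _economic_result(norm_row: pd.Series, cfg: RunConfig):
    labels = {v: _label_value(norm_row[f"{v}_fz"], cfg.sets_for(v)) for v in ECON_VARS}
    return classify_economic(labels, cfg)


def _food_result(norm_row: pd.Series, cfg: RunConfig):
    nut_sets = cfg.sets_for("nutrition")
    aff_sets = cfg.sets_for("affordability")
    nut_labels = {k: _label_value(norm_row[f"c_{k}_fz"], nut_sets) for k in NUTRIENTS}
    aff_labels = {k: _label_value(norm_row[f"a_{k}_fz"], aff_sets) for k in NUTRIENTS}
    _, nut_cls = classify_subindex(nut_labels, cfg.nutrition_rules)
    _, aff_cls = classify_subindex(aff_labels, cfg.affordability_rules)
    labels = {
        "gov_list": "included" if norm_row["gov_included"] >= 0.5 else "not_included",
        "traditional": _label_value(norm_row["traditional_fz"], cfg.sets_for("traditional")),
        "nutrition": nut_cls,
        "affordability": aff_cls,
    }
    return classify_food_security(labels, cfg)


@dataclass
class PipelineOutputs:
    indicators: pd.DataFrame
    pillars: pd.DataFrame
    audit: pd.DataFrame
    ranked: pd.DataFrame
    summary: dict


def _crop_group_map(species: pd.DataFrame, cfg: RunConfig) -> dict[str, str]:
    """species id -> gene-pool key (configured crop group, else genus)."""
    genus_to_group = {g: grp for grp, genera in cfg.crop_groups.items() for g in genera}
    return {sid: genus_to_group.get(genus, genus)
            for sid, genus in species["genus"].items()}


def run_pipeline(cfg: RunConfig, ds: Dataset, output_dir: str | Path | None = None,
                 blend: bool = False) -> PipelineOutputs:
    """Indicators -> normalization -> fuzzification -> pillars -> imputation
    -> final ranking.  Deterministic for identical inputs."""
    for flag in ("invert_affordability", "geographic_overrides", "crop_groups"):
        log.info("config %s = %r", flag, getattr(cfg, flag))

    raw = compute_indicators(ds, cfg)
    norm = normalize_indicators(raw, ds.species, cfg)
    crop_group = _crop_group_map(ds.species, cfg)

    # geographic + vulnerability (categorical pillars)
    geo_labels = {}
    for sid in ds.species.index:
        if sid in cfg.geographic_overrides:
            geo_labels[sid] = cfg.geographic_overrides[sid]
            log.info("geographic override for %s -> %s", sid, geo_labels[sid])
        else:
            geo_labels[sid] = classify_geographic(ds.regions_of(sid)).label
    vul = ds.vulnerability.set_index("species_id") if len(ds.vulnerability) else None
    vul_labels = {}
    for sid in ds.species.index:
        nat = intl = None
        if vul is not None and sid in vul.index:
            r = vul.loc[sid]
            nat = r["national"] if pd.notna(r["national"]) else None
            intl = r["international"] if pd.notna(r["international"]) else None
        vul_labels[sid] = classify_vulnerability(nat, intl).merged

    # pre-imputation pillar results from each species' own data
    econ_own = {sid: _economic_result(norm.loc[sid], cfg) for sid in norm.index}
    food_own = {sid: _food_result(norm.loc[sid], cfg) for sid in norm.index}

    # imputation: economic and food variable blocks, geographic label level
    econ_cols = [f"{v}_fz" for v in ECON_VARS]
    food_trigger = (["traditional_fz"] + [f"c_{k}_fz" for k in NUTRIENTS]
                    + [f"a_{k}_fz" for k in NUTRIENTS])
    # a known government-list status alone does not make a species
    # data-bearing, but an unknown status is borrowed along with the rest
    food_cols = food_trigger + ["gov_included"]
    econ_di = pd.Series({s: r.decision_index for s, r in econ_own.items()})
    food_di = pd.Series({s: r.decision_index for s, r in food_own.items()})
    filled_econ, tags_econ, audit_econ = apply_imputation(
        norm[econ_cols], ds.species, econ_di, "economic", crop_group)
    filled_food, tags_food, audit_food = apply_imputation(
        norm[food_cols], ds.species, food_di, "food_security", crop_group,
        trigger_columns=food_trigger)

    geo_level = pd.Series({s: ORDINAL_SCALE["geographic"].get(l, math.nan)
                           for s, l in geo_labels.items()}, dtype=float)
    geo_level[geo_level == 0] = math.nan  # undetermined = no data
    geo_frame = geo_level.to_frame("geo_level")
    filled_geo, tags_geo, audit_geo = apply_imputation(
        geo_frame, ds.species, geo_level, "geographic", crop_group)
    level_to_label = {v: k for k, v in ORDINAL_SCALE["geographic"].items()}
    final_geo = {sid: (level_to_label[int(filled_geo.at[sid, "geo_level"])]
                       if pd.notna(filled_geo.at[sid, "geo_level"]) else UNDETERMINED)
                 for sid in ds.species.index}

    # post-imputation classification on the filled variable blocks
    post = norm.copy()
    post[econ_cols] = filled_econ
    post[food_cols] = filled_food
    econ_final = {sid: _economic_result(post.loc[sid], cfg) for sid in post.index}
    food_final = {sid: _food_result(post.loc[sid], cfg) for sid in post.index}

    pillar_rows = {}
    for sid in ds.species.index:
        pillar_rows[sid] = {
            "geographic_label": final_geo[sid],
            "geographic_uncertainty": tags_geo[sid],
            "vulnerability_label": vul_labels[sid],
            "vulnerability_uncertainty": "reliable",
            "economic_label": econ_final[sid].label,
            "economic_decision_index": econ_final[sid].decision_index,
            "economic_uncertainty": tags_econ[sid],
            "food_security_label": food_final[sid].label,
            "food_security_decision_index": food_final[sid].decision_index,
            "food_security_uncertainty": tags_food[sid],
        }
    pillar_table = pd.DataFrame.from_dict(pillar_rows, orient="index")
    pillar_table.index.name = "species_id"

    ranked = rank_all(pillar_table, cfg, blend=blend)
    ranked.insert(0, "group", ds.species["group"].reindex(ranked.index))

    audit = pd.concat([audit_econ, audit_food, audit_geo], ignore_index=True)
    norm_out = norm.copy()
    norm_out["missing_economic"] = norm[econ_cols].isna().all(axis=1)
    norm_out["missing_food"] = norm[food_trigger].isna().all(axis=1)

    summary = {
        "n_species": int(len(ds.species)),
        "final_class_counts": {
            grp: ranked.loc[ranked["group"] == grp, "final_class"]
                       .value_counts().to_dict()
            for grp in sorted(ds.species["group"].unique())
        },
        "uncertainty_counts": {
            p: pillar_table[f"{p}_uncertainty"].value_counts().to_dict()
            for p in ("geographic", "economic", "food_security")
        },
        "pillar_label_counts": {
            p: pillar_table[f"{p}_label"].value_counts().to_dict()
            for p in ("geographic", "vulnerability", "economic", "food_security")
        },
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        norm_out.to_csv(out / "indicators.csv")
        pillar_table.to_csv(out / "pillars.csv")
        audit.to_csv(out / "imputation_audit.csv", index=False)
        ranked.to_csv(out / "ranked.csv")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return PipelineOutputs(norm_out, pillar_table, audit, ranked, summary)
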