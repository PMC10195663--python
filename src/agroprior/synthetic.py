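"""Synthetic fixture datasets with planted ground truth.

The generator emulates the tabular structure the index consumes — a species
registry with genus structure and FAO categories, regions of diversity,
red-list records, agricultural statistics, food composition, government-list
membership and traditional-consumption counts — not the statistics of any
real agricultural economy.  For every species a target label is drawn per
variable FIRST and raw values are then constructed so the computed,
normalized indicator lands strictly inside that label's membership plateau
(grade exactly 1), which makes label recovery deterministic and gives exact
ground truth.  Pillar-level missingness is applied afterwards at the study's
observed rates (62% economic, 73% food security by default).

Affordability is the one variable the pipeline range-normalizes per
nutrient; the generator keeps price/content separable across nutrients
(price_i proportional to a per-species factor t_i, content_ij proportional
to the nutrient's daily target) and pins the observed range of t at exactly
[1, 100] with two anchor species, so the normalized affordability of every
species equals its planted value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import vocab
from .config import NormalizationSpec, RunConfig, default_config
from .fuzzy_core import MembershipFunction, Shape

__all__ = ["GeneratorSpec", "generate", "write_dataset"]

_CONSUMPTION_G_DAY = 100.0  # fixed daily consumption used by the generator

#: fixed per-variable label combinations realising each planted pillar class
_ECON_COMBOS = {  # homogeneous: ID = s/4 lands in the namesake interval
    "low": {"lafay": "low", "yield": "low", "income": "low", "coverage": "narrow"},
    "medium": {"lafay": "medium", "yield": "medium", "income": "medium",
               "coverage": "medium"},
    "high": {"lafay": "high", "yield": "high", "income": "high", "coverage": "large"},
}
_FOOD_COMBOS = {  # scores 0/1/3 for gov and traditional, 0..3 for the sub-indices
    "low": {"gov_list": "not_included", "traditional": "medium",
            "nutrition": "medium", "affordability": "medium"},      # ID = 5/16
    "medium": {"gov_list": "included", "traditional": "medium",
               "nutrition": "medium", "affordability": "medium"},   # ID = 8/16
    "high": {"gov_list": "included", "traditional": "large",
             "nutrition": "high", "affordability": "high"},         # ID = 12/16
}
#: anchor overrides pinning the affordability normalization range
_ANCHOR_HIGH = {"gov_list": "included", "traditional": "large",
                "nutrition": "high", "affordability": "high"}        # t = 100
_ANCHOR_LOW = {"gov_list": "not_included", "traditional": "large",
               "nutrition": "medium", "affordability": "undetermined"}  # t = 1, ID = 5/16


@dataclass
class GeneratorSpec:
    n_species: int = 345
    fraction_ncb: float = 70 / 345
    missingness_economic: float = 0.62
    missingness_food: float = 0.73
    missingness_geographic: float = 0.0
    ensure_donors: bool = False
    hard_mode: bool = False  # sample from ramps instead of plateaus
    mean_genus_size: float = 2.5  # geometric genus-size distribution (BGVCOL)
    seed: int = 0
    class_probs: dict = field(default_factory=lambda: {
        "geographic": (("local", 0.45), ("close", 0.25), ("distant", 0.30)),
        "vulnerability": (("threatened", 0.10), ("minor_concern", 0.30),
                          ("not_evaluated", 0.60)),
        "economic": (("low", 0.40), ("medium", 0.35), ("high", 0.25)),
        "food_security": (("low", 0.40), ("medium", 0.35), ("high", 0.25)),
    })

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be at least 4")
        for frac in (self.fraction_ncb, self.missingness_economic,
                     self.missingness_food, self.missingness_geographic):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


def synthetic_config() -> RunConfig:
    """Config matching the generator's value scales: raw values are emitted
    directly on the fuzzification scale, so only affordability (per-nutrient
    price ratios) needs range normalization."""
    cfg = default_config()
    cfg.total_municipalities = 1000
    cfg.normalization = {
        "affordability": NormalizationSpec(method="range_1_100"),
    }
    return cfg


def _sample_plateau(mf: MembershipFunction, rng: np.random.Generator,
                    hard: bool = False, hi_cap: float | None = None) -> float:
    """A value with membership grade exactly 1 (or, in hard mode, anywhere
    in the support, exercising ramps and tie-breaks)."""
    if mf.shape is Shape.SINGLETON:
        return mf.a
    lo, hi = (mf.a, mf.b) if hard else (mf.m, mf.n)
    if hi_cap is not None:
        hi = min(hi, hi_cap)
    if not hard:
        pad = 0.03 * (hi - lo)
        lo, hi = lo + pad, hi - pad
    if hi <= lo:
        return lo
    return float(rng.uniform(lo, hi))


def _draw(rng: np.random.Generator, probs) -> str:
    labels, p = zip(*probs)
    return str(rng.choice(labels, p=np.array(p) / np.sum(p)))


def _final_class_of(geo: str, vul: str, econ: str, food: str) -> str:
    """Ground-truth priority class, written out independently of the ranking
    module."""
    level = {
        "geo": {"undetermined": 0, "distant": 1, "close": 2, "local": 3}[geo],
        "vul": {"not_evaluated": 0, "minor_concern": 1, "threatened": 3}[vul],
        "econ": {"undetermined": 0, "low": 1, "medium": 2, "high": 3}[econ],
        "food": {"undetermined": 0, "low": 1, "medium": 2, "high": 3}[food],
    }
    n_high = sum(1 for v in level.values() if v >= 3)
    if n_high >= 3:
        return "high"
    others_mid = sum(1 for k in ("vul", "econ", "food") if level[k] >= 2)
    if level["geo"] >= 2 and others_mid >= 2:
        return "medium"
    return "low"


def generate(spec: GeneratorSpec) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, RunConfig]:
    """Build the input tables, the ground-truth table and a matching config."""
    rng = np.random.default_rng(spec.seed)
    cfg = synthetic_config()
    n = spec.n_species
    n_ncb = int(round(spec.fraction_ncb * n))

    # --- registry: NCB species are unique crops (singleton genera); BGVCOL
    # genera follow a geometric size distribution (>= 2 with ensure_donors)
    ids = [f"sp{i:04d}" for i in range(n)]
    genera: list[str] = []
    gi = 0
    n_bgv = n - n_ncb
    while len(genera) < n_bgv:
        size = int(rng.geometric(1.0 / spec.mean_genus_size))
        if spec.ensure_donors:
            size = max(size, 2)
        size = min(size, n_bgv - len(genera))
        if spec.ensure_donors and size == 1 and genera:
            genera.append(genera[-1])  # fold a stranded singleton into the last genus
            continue
        genera.extend([f"genus{gi:03d}"] * size)
        gi += 1
    genera += [f"ncbgenus{i:03d}" for i in range(n_ncb)]
    groups = [vocab.BGVCOL] * n_bgv + [vocab.NCB] * n_ncb
    fao = list(sorted(vocab.FAO_CATEGORIES))
    genus_fao = {g: fao[int(rng.integers(len(fao)))] for g in dict.fromkeys(genera)}
    species = pd.DataFrame({
        "species_id": ids,
        "taxon": [f"Taxon {g} {i}" for i, g in enumerate(genera)],
        "group": groups,
        "genus": genera,
        "fao_category": [genus_fao[g] for g in genera],
    })

    mfs = {v: {s.label: s.to_set().function for s in cfg.membership[v]}
           for v in cfg.membership}
    truth_rows, region_rows, vul_rows = [], [], []
    econ_rows, nut_rows, gov_rows, trad_rows = [], [], [], []

    local_list = sorted(vocab.LOCAL_REGIONS)
    close_list = sorted(vocab.CLOSE_REGIONS)
    distant_list = sorted(vocab.DISTANT_REGIONS)

    for i, sid in enumerate(ids):
        geo = _draw(rng, spec.class_probs["geographic"])
        vul = _draw(rng, spec.class_probs["vulnerability"])
        econ = _draw(rng, spec.class_probs["economic"])
        food = _draw(rng, spec.class_probs["food_security"])

        # regions (precedence: a local species may also list a distant region)
        if geo == "local":
            region_rows.append({"species_id": sid,
                                "region": local_list[int(rng.integers(2))]})
            if rng.random() < 0.3:
                region_rows.append({"species_id": sid,
                                    "region": distant_list[int(rng.integers(len(distant_list)))]})
        elif geo == "close":
            region_rows.append({"species_id": sid,
                                "region": close_list[int(rng.integers(3))]})
        else:
            for r in rng.choice(distant_list, size=int(rng.integers(1, 3)),
                                replace=False):
                region_rows.append({"species_id": sid, "region": str(r)})

        # vulnerability sources
        if vul == "threatened":
            if rng.random() < 0.5:
                vul_rows.append({"species_id": sid,
                                 "national": str(rng.choice(["endangered", "vulnerable"])),
                                 "international": None})
            else:
                vul_rows.append({"species_id": sid, "national": None,
                                 "international": str(rng.choice(
                                     ["critically endangered", "endangered", "vulnerable"]))})
        elif vul == "minor_concern":
            if rng.random() < 0.5:
                vul_rows.append({"species_id": sid, "national": "minor concern",
                                 "international": None})
            else:
                vul_rows.append({"species_id": sid, "national": None,
                                 "international": str(rng.choice(
                                     ["near threatened", "least concern"]))})

        # economic raw tables inverted from the planted per-variable labels
        ecombo = _ECON_COMBOS[econ]
        inc_v = _sample_plateau(mfs["income"][ecombo["income"]], rng, spec.hard_mode)
        yld_v = _sample_plateau(mfs["yield"][ecombo["yield"]], rng, spec.hard_mode)
        laf_v = _sample_plateau(mfs["lafay"][ecombo["lafay"]], rng, spec.hard_mode)
        cov_u = _sample_plateau(mfs["coverage"][ecombo["coverage"]], rng,
                                spec.hard_mode, hi_cap=99.5)
        municipalities = int(round(cov_u * cfg.total_municipalities / 100.0))
        area, production = 1.0, yld_v
        price = inc_v / yld_v
        # Lafay = Pd/(Pd + M - X): solve imports/exports for the target ratio
        if laf_v >= 1.0:
            imports, exports = 0.0, production * (1.0 - 1.0 / laf_v)
        else:
            imports, exports = production * (1.0 / laf_v - 1.0), 0.0
        for year in (2015, 2016, 2017):
            econ_rows.append({"species_id": sid, "year": year,
                              "production_t": production, "area_ha": area,
                              "price_usd_per_t": price, "imports_t": imports,
                              "exports_t": exports, "municipalities": municipalities})

        # food raw tables
        fcombo = dict(_FOOD_COMBOS[food])
        if i == 0:
            fcombo, food = dict(_ANCHOR_HIGH), "high"
        elif i == 1:
            fcombo, food = dict(_ANCHOR_LOW), "low"
        c_val = _sample_plateau(mfs["nutrition"][fcombo["nutrition"]], rng,
                                spec.hard_mode)
        if i == 0:
            t_val = 100.0
        elif i == 1:
            t_val = 1.0
        else:
            t_val = _sample_plateau(mfs["affordability"][fcombo["affordability"]],
                                    rng, spec.hard_mode)
        contents = {k: c_val * cfg.daily_targets[k] / _CONSUMPTION_G_DAY
                    for k in ("ca", "fe", "zn", "energy")}
        price_100g = t_val * c_val / _CONSUMPTION_G_DAY
        nut_rows.append({"species_id": sid, "ca_mg": contents["ca"],
                         "fe_mg": contents["fe"], "zn_mg": contents["zn"],
                         "energy_kcal": contents["energy"],
                         "consumption_g_day": _CONSUMPTION_G_DAY,
                         "price_usd_100g": price_100g})
        gov_rows.append({"species_id": sid,
                         "included": 1 if fcombo["gov_list"] == "included" else 0})
        trad_rows.append({"species_id": sid,
                          "regions_count": _sample_plateau(
                              mfs["traditional"][fcombo["traditional"]], rng,
                              spec.hard_mode)})

        truth_rows.append({
            "species_id": sid, "group": groups[i], "genus": genera[i],
            "geographic_label": geo, "vulnerability_label": vul,
            "economic_label": econ, "food_security_label": food,
            "final_class": _final_class_of(geo, vul, econ, food),
            **{f"var_{k}": v for k, v in ecombo.items()},
            **{f"var_{k}": v for k, v in fcombo.items()},
        })

    tables = {
        "species": species,
        "regions": pd.DataFrame(region_rows, columns=["species_id", "region"]),
        "vulnerability": pd.DataFrame(vul_rows,
                                      columns=["species_id", "national", "international"]),
        "economics": pd.DataFrame(econ_rows),
        "nutrition": pd.DataFrame(nut_rows),
        "government_list": pd.DataFrame(gov_rows),
        "traditional": pd.DataFrame(trad_rows),
    }
    truth = pd.DataFrame(truth_rows).set_index("species_id")

    # --- pillar-level missingness (blank the species' rows of a table group)
    mask_econ = rng.random(n) < spec.missingness_economic
    mask_food = rng.random(n) < spec.missingness_food
    mask_geo = rng.random(n) < spec.missingness_geographic
    if spec.ensure_donors:
        mask_food[:2] = False  # keep the normalization anchors intact
        for mask in (mask_econ, mask_food, mask_geo):
            for genus, sub in species[species["group"] == vocab.BGVCOL].groupby("genus"):
                pos = [ids.index(s) for s in sub["species_id"]]
                if all(mask[p] for p in pos):
                    mask[min(pos)] = False

    def _blank(table: str, mask: np.ndarray) -> None:
        masked_ids = {ids[i] for i in range(n) if mask[i]}
        df = tables[table]
        tables[table] = df[~df["species_id"].isin(masked_ids)].reset_index(drop=True)

    _blank("economics", mask_econ)
    for t in ("nutrition", "government_list", "traditional"):
        _blank(t, mask_food)
    _blank("regions", mask_geo)
    truth["masked_economic"] = mask_econ
    truth["masked_food"] = mask_food
    truth["masked_geographic"] = mask_geo
    return tables, truth, cfg


def write_dataset(tables: dict[str, pd.DataFrame], truth: pd.DataFrame,
                  cfg: RunConfig, out_dir: str | Path) -> None:
    """Write the generated tables as the input-directory CSV layout, the
    ground truth as truth.csv, and the matching config as config.yaml."""
    from .config import save_config

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    truth.to_csv(out / "truth.csv")
    save_config(cfg, out / "config.yaml")
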