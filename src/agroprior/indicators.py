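"""Per-species economic and nutritional indicators.

Raw agricultural-statistics and food-composition tables are reduced to one
value per species per variable: income per hectare, trade-balance (Lafay)
index, municipality coverage, yield, percent contribution to daily
micronutrient targets, and nutrient-price ratios.  Missing inputs propagate
as missing (NaN) so the downstream "undetermined" handling is exercised
instead of raising.

Also provides range normalization onto [1, 100] and a deterministic,
globally optimal 1-D k-means (dynamic programming) used to calibrate label
boundaries for new variables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "income",
    "lafay",
    "municipality_coverage",
    "crop_yield",
    "nutritional_contribution",
    "nutrient_price_ratio",
    "range_normalize",
    "ckmeans_1d",
    "ClusterResult",
]

log = logging.getLogger(__name__)

MISSING = float("nan")


def _missing(*vals: float | None) -> bool:
    return any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals)


def income(price: float | None, production: float | None, area: float | None) -> float:
    """Income per hectare, Inc = (P * Pr) / A  [USD/ha].

    P is the sales price (USD/t), Pr the annual production (t) and A the
    harvested area (ha).  Missing inputs or zero area yield missing.
    """
    if _missing(price, production, area) or area == 0:
        return MISSING
    return price * production / area


def lafay(production: float | None, imports: float | None, exports: float | None) -> float:
    """Contribution to the trade balance, Li = Pd / (Pd + M - X).

    The ratio of production to apparent consumption (production + imports -
    exports).  Values above 1 mark a net exporter; the ratio may be negative
    or large when exports exceed apparent supply.  A zero denominator is
    logged and returned as missing.
    """
    if _missing(production, imports, exports):
        return MISSING
    denom = production + imports - exports
    if denom == 0:
        log.warning("lafay denominator zero (Pd=%s M=%s X=%s); treated as missing",
                    production, imports, exports)
        return MISSING
    return production / denom


def municipality_coverage(n_municipalities: float | None, total_municipalities: float) -> float:
    """Percent of municipalities cultivating the species, CM = M/TM * 100."""
    if total_municipalities <= 0:
        raise ValueError("total municipality count must be positive")
    if _missing(n_municipalities):
        return MISSING
    if not 0 <= n_municipalities <= total_municipalities:
        raise ValueError(
            f"municipality count {n_municipalities} outside [0, {total_municipalities}]"
        )
    return n_municipalities / total_municipalities * 100.0


def crop_yield(production: Sequence[float], area: Sequence[float]) -> float:
    """Mean annual production over mean harvested area, R = mean(Pr)/mean(A).

    Multi-year series are averaged over the years with data before the
    division; an empty or all-zero area series yields missing.
    """
    pr = [v for v in production if not _missing(v)]
    ar = [v for v in area if not _missing(v)]
    if not pr or not ar:
        return MISSING
    mean_area = sum(ar) / len(ar)
    if mean_area == 0:
        return MISSING
    return (sum(pr) / len(pr)) / mean_area


def nutritional_contribution(
    consumption_g_day: float | None, content_per_100g: float | None, daily_target: float
) -> float:
    """Percent of the daily micronutrient target met by daily consumption.

    AD = CD * M / 100 (mg/day actually ingested), C = AD / MN * 100 (% of the
    daily target MN).
    """
    if daily_target <= 0:
        raise ValueError("daily micronutrient target must be positive")
    if _missing(consumption_g_day, content_per_100g):
        return MISSING
    daily_amount = consumption_g_day * content_per_100g / 100.0
    return daily_amount / daily_target * 100.0


def nutrient_price_ratio(price_per_100g: float | None, content_per_100g: float | None) -> float:
    """Consumer price per unit of nutrient in a 100 g edible portion.

    Zero content means the nutrient is absent and affordability is undefined
    (missing); a zero price is a valid free food.
    """
    if _missing(price_per_100g, content_per_100g) or content_per_100g == 0:
        return MISSING
    return price_per_100g / content_per_100g


def range_normalize(values: Sequence[float]) -> list[float]:
    """Affine map of the observed range onto [1, 100].

    min -> 1, max -> 100, NaN passes through.  If every finite value is
    identical the map is undefined; all collapse to 1 with a warning.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    out = np.full_like(arr, np.nan)
    if finite.size == 0:
        return out.tolist()
    lo, hi = float(finite.min()), float(finite.max())
    mask = np.isfinite(arr)
    if hi == lo:
        log.warning("range_normalize: all %d values identical (%s); mapping to 1", finite.size, lo)
        out[mask] = 1.0
        return out.tolist()
    out[mask] = 1.0 + 99.0 * (arr[mask] - lo) / (hi - lo)
    return out.tolist()


@dataclass(frozen=True)
class ClusterResult:
    """Globally optimal order-preserving 1-D partition into k clusters."""

    k: int
    assignments: tuple[int, ...]  # cluster rank (1 = lowest centroid) per input value
    centroids: tuple[float, ...]  # strictly increasing
    within_ss: float


def ckmeans_1d(values: Sequence[float], k: int) -> ClusterResult:
    """Optimal 1-D k-means by dynamic programming (no seed, deterministic).

    Sorting makes optimal clusters contiguous; the DP minimises total
    within-cluster sum of squares exactly, unlike Lloyd's algorithm.
    Requires at least ``k`` distinct values.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("ckmeans_1d expects a non-empty 1-D sequence")
    if not np.all(np.isfinite(vals)):
        raise ValueError("ckmeans_1d requires finite values")
    if np.unique(vals).size < k:
        raise ValueError(f"need at least k={k} distinct values, got {np.unique(vals).size}")

    order = np.argsort(vals, kind="stable")
    x = vals[order]
    n = x.size
    # prefix sums -> O(1) within-SS of any contiguous segment [i, j]
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_ss(i: int, j: int) -> float:  # inclusive indices into x
        s = cs[j + 1] - cs[i]
        s2 = cs2[j + 1] - cs2[i]
        m = j - i + 1
        return max(s2 - s * s / m, 0.0)

    INF = float("inf")
    cost = np.full((k + 1, n), INF)
    back = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        cost[1, j] = seg_ss(0, j)
    for q in range(2, k + 1):
        for j in range(q - 1, n):
            # last cluster is x[i..j]
            best, arg = INF, q - 1
            for i in range(q - 1, j + 1):
                c = cost[q - 1, i - 1] + seg_ss(i, j)
                if c < best:
                    best, arg = c, i
            cost[q, j], back[q, j] = best, arg

    # recover boundaries
    bounds = []
    j = n - 1
    for q in range(k, 0, -1):
        i = back[q, j] if q > 1 else 0
        bounds.append((i, j))
        j = i - 1
    bounds.reverse()

    centroids = tuple(float(x[i:j + 1].mean()) for i, j in bounds)
    rank_sorted = np.empty(n, dtype=int)
    for rank, (i, j) in enumerate(bounds, start=1):
        rank_sorted[i:j + 1] = rank
    assignments = np.empty(n, dtype=int)
    assignments[order] = rank_sorted
    return ClusterResult(k=k, assignments=tuple(int(a) for a in assignments),
                         centroids=centroids, within_ss=float(cost[k, n - 1]))
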