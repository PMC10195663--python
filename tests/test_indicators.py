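import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agroprior import indicators as ind


def is_missing(v):
    return isinstance(v, float) and math.isnan(v)


class TestArithmetic:
    @pytest.mark.parametrize("args, expected", [
        ((500, 20, 4), 2500.0),
        ((500, 0, 4), 0.0),
        ((500, 20, None), None),   # missing area propagates
        ((500, 20, 0), None),      # zero area undefined
    ])
    def test_income(self, args, expected):
        got = ind.income(*args)
        assert is_missing(got) if expected is None else got == pytest.approx(expected)

    @pytest.mark.parametrize("args, expected", [
        ((100, 0, 0), 1.0),              # autarky
        ((100, 50, 0), 2 / 3),           # net importer < 1
        ((100, 0, 50), 2.0),             # net exporter > 1
        ((100, 0, 200), -1.0),           # exports exceed apparent supply
        ((100, None, 0), None),
        ((100, 0, 100), None),           # zero denominator -> missing
    ])
    def test_lafay(self, args, expected):
        got = ind.lafay(*args)
        assert is_missing(got) if expected is None else got == pytest.approx(expected)

    @pytest.mark.parametrize("m, tm, expected", [
        (1122, 1122, 100.0), (0, 1122, 0.0), (561, 1122, 50.0),
    ])
    def test_coverage(self, m, tm, expected):
        assert ind.municipality_coverage(m, tm) == pytest.approx(expected)

    def test_coverage_rejects_impossible_count(self):
        with pytest.raises(ValueError):
            ind.municipality_coverage(2000, 1122)
        with pytest.raises(ValueError):
            ind.municipality_coverage(5, 0)

    def test_crop_yield(self):
        assert ind.crop_yield([120], [10]) == pytest.approx(12.0)
        assert ind.crop_yield([0, 0], [10, 10]) == 0.0
        assert is_missing(ind.crop_yield([], []))
        assert is_missing(ind.crop_yield([5], [0]))

    def test_crop_yield_partial_years_matches_loop_mean(self):
        pr = [100, float("nan"), 140]
        ar = [10, 12, float("nan")]
        pr_clean = [v for v in pr if not math.isnan(v)]
        ar_clean = [v for v in ar if not math.isnan(v)]
        expected = (sum(pr_clean) / len(pr_clean)) / (sum(ar_clean) / len(ar_clean))
        assert ind.crop_yield(pr, ar) == pytest.approx(expected)

    def test_nutritional_contribution(self):
        assert ind.nutritional_contribution(200, 50, 1000) == pytest.approx(10.0)
        assert ind.nutritional_contribution(0, 50, 1000) == 0.0
        assert is_missing(ind.nutritional_contribution(200, None, 1000))
        with pytest.raises(ValueError):
            ind.nutritional_contribution(200, 50, 0)

    def test_nutrient_price_ratio(self):
        assert ind.nutrient_price_ratio(0.50, 50) == pytest.approx(0.01)
        assert is_missing(ind.nutrient_price_ratio(0.50, 0))
        assert ind.nutrient_price_ratio(0.0, 50) == 0.0


class TestRangeNormalize:
    def test_endpoints_and_midpoint(self):
        out = ind.range_normalize([2, 6, 10])
        assert out == pytest.approx([1.0, 50.5, 100.0])

    def test_identical_values_collapse_to_floor(self):
        assert ind.range_normalize([3, 3, 3]) == pytest.approx([1, 1, 1])

    def test_nan_passthrough(self):
        out = ind.range_normalize([1, float("nan"), 3])
        assert out[0] == 1.0 and math.isnan(out[1]) and out[2] == 100.0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=20, unique=True))
    def test_affine_preserves_difference_ratios(self, values):
        out = ind.range_normalize(values)
        v0, v1, v2 = values[:3]
        if abs(v2 - v1) > 1e-9 * max(1, abs(v1), abs(v2)):
            expected = (v1 - v0) / (v2 - v1)
            got = (out[1] - out[0]) / (out[2] - out[1])
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-6)


def brute_force_k3_sse(values):
    """Exhaustive search over all order-preserving 3-partitions."""
    x = sorted(values)
    n = len(x)

    def sse(seg):
        mu = sum(seg) / len(seg)
        return sum((v - mu) ** 2 for v in seg)

    return min(sse(x[:i]) + sse(x[i:j]) + sse(x[j:])
               for i, j in itertools.combinations(range(1, n), 2))


class TestCkmeans:
    def test_well_separated_groups(self):
        res = ind.ckmeans_1d([1, 2, 10, 11, 100, 101], k=3)
        assert res.assignments == (1, 1, 2, 2, 3, 3)
        assert res.centroids == pytest.approx((1.5, 10.5, 100.5))

    def test_k_equals_distinct_values(self):
        res = ind.ckmeans_1d([5, 1, 9], k=3)
        assert res.centroids == pytest.approx((1, 5, 9))
        assert res.within_ss == pytest.approx(0.0)

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            ind.ckmeans_1d([1, 1, 2, 2], k=3)

    def test_centroids_strictly_increasing_and_order_preserved(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        res = ind.ckmeans_1d(x, k=4)
        assert all(a < b for a, b in zip(res.centroids, res.centroids[1:]))
        # lower values never land in a higher-ranked cluster than higher values
        order = np.argsort(x)
        ranks = np.array(res.assignments)[order]
        assert all(r1 <= r2 for r1, r2 in zip(ranks, ranks[1:]))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 26))
            x = rng.normal(scale=10, size=n)
            res = ind.ckmeans_1d(x, k=3)
            assert res.within_ss == pytest.approx(brute_force_k3_sse(x), rel=1e-9)

    def test_beats_or_ties_lloyds(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.exponential(size=30)
            res = ind.ckmeans_1d(x, k=3)
            km = KMeans(n_clusters=3, n_init=1, random_state=0).fit(x.reshape(-1, 1))
            assert res.within_ss <= km.inertia_ + 1e-9
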