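"""Mann-Kendall statistics, area series, site summaries, crosstabs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swirmap import (
    AreaSeries,
    covariate_crosstab,
    inundated_area_series,
    lag1_autocorr,
    mann_kendall,
    site_summary,
)
from swirmap.classifier import NODATA_LABEL, InundationMap


def brute_force_mk(x):
    """Independent pair-enumeration / tie-counting oracle for S and Var(S)."""
    x = list(x)
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] > x[i]:
                s += 1
            elif x[j] < x[i]:
                s -= 1
    groups = {}
    for v in x:
        groups[v] = groups.get(v, 0) + 1
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in groups.values() if t > 1)
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    return s, var_s


class TestMannKendall:
    @pytest.mark.filterwarnings("ignore:Mann-Kendall on n")
    def test_strictly_increasing_five_points(self):
        res = mann_kendall([1, 2, 3, 4, 5])
        assert res.S == 10
        assert res.varS == pytest.approx(50 / 3)
        assert res.Zc == pytest.approx(9 / math.sqrt(50 / 3))
        assert res.trend_class == "significantly_increasing"
        assert res.p < 0.05

    def test_constant_series_is_no_trend(self):
        res = mann_kendall([2.0] * 10)
        assert res.S == 0 and res.Zc == 0.0
        assert res.trend_class == "no_trend"
        assert res.p == pytest.approx(1.0)

    def test_n_below_three_errors(self):
        with pytest.raises(ValueError):
            mann_kendall([1, 2])

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="small"):
            mann_kendall([1, 3, 2, 5, 4])

    def test_oracle_equivalence_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(8, 40))
            x = rng.normal(size=n)
            if rng.random() < 0.5:  # inject ties
                x = np.round(x, 1)
            res = mann_kendall(x)
            s, var_s = brute_force_mk(x)
            assert res.S == s
            assert res.varS == var_s
            expected_zc = 0.0 if s == 0 else (s - np.sign(s)) / math.sqrt(var_s)
            assert res.Zc == pytest.approx(expected_zc, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=8, max_size=25
        )
    )
    def test_antisymmetry(self, values):
        fwd = mann_kendall(values)
        rev = mann_kendall(values[::-1])
        assert rev.S == -fwd.S
        assert rev.Zc == pytest.approx(-fwd.Zc)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.001, max_value=1e3, allow_nan=False),
            min_size=8,
            max_size=25,
        ),
        st.floats(min_value=0.01, max_value=100),
    )
    def test_scale_invariance(self, values, factor):
        # Positive rescaling preserves every pairwise order, hence the verdict.
        a = mann_kendall(values)
        b = mann_kendall([factor * v for v in values])
        assert b.S == a.S
        assert b.varS == a.varS
        assert b.Zc == pytest.approx(a.Zc)
        assert b.trend_class == a.trend_class

    def test_sign_of_zc_matches_sign_of_s(self):
        # The +-1 continuity correction sends |S| <= 1 to Zc = 0; otherwise
        # Zc carries the sign of S.
        rng = np.random.default_rng(5)
        for _ in range(20):
            res = mann_kendall(rng.normal(size=15))
            if res.Zc != 0.0:
                assert np.sign(res.Zc) == np.sign(res.S)
            else:
                assert abs(res.S) <= 1

    def test_prewhitening_reduces_ar1_inflation(self):
        rng = np.random.default_rng(17)
        x = np.zeros(200)
        for t in range(1, 200):
            x[t] = 0.8 * x[t - 1] + rng.normal()
        plain = mann_kendall(x)
        pw = mann_kendall(x, prewhiten=True)
        assert plain.r1_flag
        assert pw.prewhitened
        assert abs(pw.Zc) <= abs(plain.Zc) + 1e-9


class TestLag1:
    def test_ar1_coefficient_recovered(self):
        rng = np.random.default_rng(3)
        x = np.zeros(5000)
        for t in range(1, 5000):
            x[t] = 0.8 * x[t - 1] + rng.normal()
        r1, flag, degen = lag1_autocorr(x)
        assert abs(r1 - 0.8) < 0.05
        assert flag and not degen

    def test_independent_noise_rarely_flags(self):
        rng = np.random.default_rng(4)
        hits = sum(
            abs(lag1_autocorr(rng.normal(size=1000)).r1) < 0.08 for _ in range(40)
        )
        assert hits >= 38  # >= 95% of replicates inside the sampling bound

    def test_zero_variance_is_degenerate(self):
        r1, flag, degen = lag1_autocorr([3.0, 3.0, 3.0, 3.0])
        assert r1 == 0.0 and not flag and degen


class TestAreaSeries:
    def _map(self, labels, year):
        return InundationMap(year=year, labels=np.asarray(labels, dtype=np.uint8))

    def test_pixel_count_to_km2(self):
        labels = np.zeros((40, 40), dtype=np.uint8)
        labels.flat[:1234] = 1
        series = inundated_area_series([self._map(labels, 2000)], 0.0009)
        assert series.areas[0] == pytest.approx(1.1106)

    def test_zero_wet_pixels(self):
        series = inundated_area_series([self._map([[0, 0]], 2000)])
        assert series.areas[0] == 0.0

    def test_nodata_contributes_zero(self):
        series = inundated_area_series([self._map([[1, NODATA_LABEL]], 2000)], 1.0)
        assert series.areas[0] == 1.0

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            inundated_area_series([])

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            AreaSeries("s", [2001, 2000], [1.0, 2.0], 0.0009)
        with pytest.raises(ValueError):
            AreaSeries("s", [2000, 2001], [1.0, -2.0], 0.0009)


class TestSiteSummary:
    def _series(self, areas, years=None):
        years = years or list(range(2000, 2000 + len(areas)))
        return AreaSeries("s", years, areas, 0.0009)

    def test_constant_series(self):
        s = site_summary(self._series([2.0, 2.0, 2.0]))
        assert s.min == s.q1 == s.mean == s.q3 == s.max == 2.0
        assert s.max_min_ratio == 1.0 and s.ratio_defined

    def test_interpolated_quartiles_on_five_points(self):
        s = site_summary(self._series([1, 2, 3, 4, 5]))
        assert (s.q1, s.mean, s.q3) == (2.0, 3.0, 4.0)
        assert s.max_min_ratio == 5.0

    def test_zero_minimum_flags_ratio_undefined(self):
        s = site_summary(self._series([0.0, 1.0, 2.0]))
        assert not s.ratio_defined
        assert math.isnan(s.max_min_ratio)

    def test_earliest_year_wins_ties(self):
        s = site_summary(self._series([5, 1, 1, 5], years=[2000, 2001, 2002, 2003]))
        assert s.year_of_min == 2001
        assert s.year_of_max == 2000


class TestCrosstab:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "trend_class", "covariate"])

    def test_single_site(self):
        tab = covariate_crosstab(
            self._table([("a", "increasing", 150.0)]), [0, 100, 200]
        )
        assert tab.loc["increasing", "[100, 200)"] == 1
        assert tab.loc["All", "All"] == 1

    def test_all_sites_one_bin(self):
        rows = [(f"s{i}", "no_trend", 50.0 + i) for i in range(5)]
        tab = covariate_crosstab(self._table(rows), [0, 100, 200])
        assert tab.loc["no_trend", "[0, 100)"] == 5
        assert (tab.drop(columns=["All", "[0, 100)"]).loc["no_trend"] == 0).all()

    def test_interior_edge_goes_to_upper_bin(self):
        tab = covariate_crosstab(
            self._table([("a", "decreasing", 100.0)]), [0, 100, 200]
        )
        assert tab.loc["decreasing", "[100, 200)"] == 1
        assert tab.loc["decreasing", "[0, 100)"] == 0

    def test_outside_values_counted_in_overflow(self):
        rows = [("a", "increasing", -5.0), ("b", "increasing", 200.0)]
        tab = covariate_crosstab(self._table(rows), [0, 100, 200])
        assert tab.loc["increasing", "overflow"] == 2  # below lo and == last edge

    def test_margins_sum(self):
        rng = np.random.default_rng(6)
        classes = ["increasing", "decreasing", "no_trend"]
        rows = [
            (f"s{i}", classes[int(rng.integers(3))], float(rng.uniform(-10, 250)))
            for i in range(30)
        ]
        tab = covariate_crosstab(self._table(rows), [0, 50, 100, 200])
        assert tab.loc["All", "All"] == 30
        body = tab.drop(index="All", columns="All")
        assert body.sum().sum() == 30
        assert (body.sum(axis=1) == tab.drop(index="All")["All"]).all()

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            covariate_crosstab(self._table([("a", "increasing", 1.0)]), [1, 1, 2])
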