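"""Similarity indices, distances, transit times and turnover statistics."""

import datetime as dt
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pharmtrace import (
    DistributionPath,
    PathMultiset,
    ccdf,
    entry_exit_rates,
    great_circle_km,
    jaccard_unique,
    jaccard_weighted,
    path_distances,
    path_length_histogram,
    transit_time_distribution,
    year_to_year_similarity,
)
from pharmtrace.stats import EARTH_RADIUS_KM, yearly_activity


def _d(n):
    return dt.date(2010, 1, 1) + dt.timedelta(days=n)


def _p(*entities, qty=1, start=0):
    dates = tuple(_d(start + i) for i in range(len(entities) - 1))
    return DistributionPath(tuple(entities), dates, qty)


def _ms(*keyed_paths):
    """Build a multiset from (key letters, multiplicity) pairs."""
    records = []
    for key, mult in keyed_paths:
        records += [_p(*key)] * mult
    return PathMultiset(records)


class TestJaccard:
    def test_identical_nonempty_is_one(self):
        a = _ms((("a", "b"), 2), (("a", "c"), 1))
        assert jaccard_unique(a, a) == 1.0
        assert jaccard_weighted(a, a) == 1.0

    def test_disjoint_is_zero(self):
        a, b = _ms((("a", "b"), 1)), _ms((("c", "d"), 1))
        assert jaccard_unique(a, b) == 0.0
        assert jaccard_weighted(a, b) == 0.0

    def test_one_shared_of_three(self):
        a = _ms((("p", "1"), 1), (("p", "2"), 1))
        b = _ms((("p", "2"), 1), (("p", "3"), 1))
        assert jaccard_unique(a, b) == pytest.approx(1 / 3)

    def test_weighted_multiplicity_formula(self):
        # multiplicities a=(2,0,1), b=(1,1,1) -> (1+0+1)/(2+1+1) = 0.5
        a = _ms((("p", "1"), 2), (("p", "3"), 1))
        b = _ms((("p", "1"), 1), (("p", "2"), 1), (("p", "3"), 1))
        assert jaccard_weighted(a, b) == pytest.approx(0.5)

    def test_empty_vs_nonempty_and_empty_vs_empty(self):
        empty, full = PathMultiset(), _ms((("a", "b"), 1))
        assert jaccard_weighted(empty, full) == 0.0
        assert jaccard_unique(empty, empty) == 1.0
        assert jaccard_weighted(empty, empty) == 1.0

    def test_quantity_weighting_option(self):
        a = PathMultiset([_p("a", "b", qty=10)])
        b = PathMultiset([_p("a", "b", qty=4)])
        assert jaccard_weighted(a, b, weight="quantity") == pytest.approx(0.4)
        assert jaccard_weighted(a, b) == 1.0

    @settings(derandomize=True, max_examples=80)
    @given(
        st.lists(st.tuples(st.integers(0, 5), st.integers(1, 4)), max_size=6),
        st.lists(st.tuples(st.integers(0, 5), st.integers(1, 4)), max_size=6),
    )
    def test_matches_brute_force_and_bounds(self, spec_a, spec_b):
        """Both indices agree with direct set/multiset enumeration, are
        symmetric, and weighted == unique for 0/1 multiplicities."""
        a = PathMultiset([_p("e", str(k)) for k, m in spec_a for _ in range(m)])
        b = PathMultiset([_p("e", str(k)) for k, m in spec_b for _ in range(m)])
        ka = Counter(r.key for r in a.records)
        kb = Counter(r.key for r in b.records)
        union = set(ka) | set(kb)
        exp_u = 1.0 if not union else len(set(ka) & set(kb)) / len(union)
        exp_w = 1.0 if not union else (
            sum(min(ka[k], kb[k]) for k in union)
            / sum(max(ka[k], kb[k]) for k in union)
        )
        assert jaccard_unique(a, b) == pytest.approx(exp_u)
        assert jaccard_weighted(a, b) == pytest.approx(exp_w)
        assert jaccard_unique(a, b) == jaccard_unique(b, a)
        assert jaccard_weighted(a, b) == jaccard_weighted(b, a)
        assert 0.0 <= jaccard_weighted(a, b) <= 1.0
        # 0/1 multiplicities collapse weighted onto unique
        ua = PathMultiset([_p("e", str(k)) for k in set(k for k, _ in spec_a)])
        ub = PathMultiset([_p("e", str(k)) for k in set(k for k, _ in spec_b)])
        assert jaccard_weighted(ua, ub) == pytest.approx(jaccard_unique(ua, ub))


class TestPathLengthHistogram:
    def test_worked_example_lengths(self, worked_result):
        hist, mean = path_length_histogram(
            PathMultiset(worked_result.completed_paths)
        )
        assert hist == {3: 2} and mean == 3.0

    def test_empty_multiset(self):
        hist, mean = path_length_histogram(PathMultiset())
        assert hist == {} and mean is None

    def test_counts_conserved_against_recount(self, small_multiset):
        hist, mean = path_length_histogram(small_multiset)
        assert sum(hist.values()) == len(small_multiset)
        brute = Counter(len(r.path) - 1 for r in small_multiset.records)
        assert hist == dict(brute)
        assert mean == pytest.approx(
            sum(k * v for k, v in brute.items()) / len(small_multiset)
        )


def _law_of_cosines_km(p, q):
    """Independent spherical-law-of-cosines oracle."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*p, *q))
    arg = (
        math.sin(lat1) * math.sin(lat2)
        + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
    )
    return EARTH_RADIUS_KM * math.acos(max(-1.0, min(1.0, arg)))


class TestGreatCircle:
    def test_zero_iff_same_point(self):
        assert great_circle_km((40.0, -75.0), (40.0, -75.0)) == 0.0
        assert great_circle_km((40.0, -75.0), (40.0, -74.9)) > 0.0

    def test_antipodal_half_circumference(self):
        assert great_circle_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, abs=1e-6
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_km((91.0, 0.0), (0.0, 0.0))

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 200:
            p = (rng.uniform(-85, 85), rng.uniform(-180, 180))
            q = (rng.uniform(-85, 85), rng.uniform(-180, 180))
            d = great_circle_km(p, q)
            if not 50.0 < d < 19_000.0:  # avoid arccos ill-conditioning
                continue
            assert d == pytest.approx(_law_of_cosines_km(p, q), abs=1e-6)
            checked += 1

    @settings(derandomize=True, max_examples=50)
    @given(
        st.tuples(st.floats(-89, 89), st.floats(-179, 179)),
        st.tuples(st.floats(-89, 89), st.floats(-179, 179)),
        st.tuples(st.floats(-89, 89), st.floats(-179, 179)),
    )
    def test_symmetry_and_triangle_inequality(self, p, q, r):
        assert great_circle_km(p, q) == pytest.approx(great_circle_km(q, p))
        assert great_circle_km(p, r) <= (
            great_circle_km(p, q) + great_circle_km(q, r) + 1e-9
        )


class TestPathDistances:
    COORDS = {
        "A": (10.0, 10.0),
        "B": (10.0, 10.0),  # same place as A
        "C": (11.0, 10.0),
    }

    def test_stationary_path_travels_zero(self):
        res = path_distances(PathMultiset([_p("A", "B", "A", "B")]), self.COORDS)
        assert res.totals == [0.0]

    def test_totals_and_step_means_with_haversine_oracle(self):
        leg_ab = great_circle_km(self.COORDS["A"], self.COORDS["C"])
        res = path_distances(PathMultiset([_p("A", "C", "C")]), self.COORDS)
        assert res.totals[0] == pytest.approx(leg_ab)
        assert res.step_means == {
            1: pytest.approx(leg_ab),
            2: pytest.approx(0.0),
        }

    def test_missing_entity_skipped_and_counted(self):
        res = path_distances(
            PathMultiset([_p("A", "Z"), _p("A", "C")]), self.COORDS
        )
        assert res.n_skipped == 1 and len(res.totals) == 1

    def test_ccdf_at_zero_is_fraction_positive(self):
        ms = PathMultiset([_p("A", "B"), _p("A", "C"), _p("A", "C")])
        res = path_distances(ms, self.COORDS)
        assert res.total_ccdf(0.0) == pytest.approx(2 / 3)


class TestCcdf:
    def test_nonincreasing_bounded_step_function(self):
        rng = np.random.default_rng(2)
        f = ccdf(rng.exponential(5.0, size=300))
        xs, ps = f.curve()
        assert np.all(np.diff(ps) <= 0)
        assert np.all((ps >= 0) & (ps <= 1))
        assert f(-1.0) == 1.0 and f(xs[-1]) == 0.0

    def test_empty_sample_undefined(self):
        with pytest.raises(ValueError):
            ccdf([])(0.0)


class TestTransitTime:
    def test_single_hop_is_zero_days(self):
        res = transit_time_distribution(PathMultiset([_p("a", "b")]))
        assert list(res.days) == [0]

    def test_worked_example_three_days(self, worked_result):
        res = transit_time_distribution(
            PathMultiset(worked_result.completed_paths)
        )
        assert list(res.days) == [3, 3]
        assert res.pdf == {3: 1.0}

    def test_pdf_sums_to_one_and_matches_ccdf(self, small_multiset):
        res = transit_time_distribution(small_multiset)
        assert sum(res.pdf.values()) == pytest.approx(1.0)
        assert res.days_ccdf(-1) == 1.0


class TestEntryExitRates:
    def test_identical_sets_no_turnover(self):
        rates = entry_exit_rates({2010: {"a", "b"}, 2011: {"a", "b"}})
        assert rates == {2011: (0.0, 0.0)}

    def test_half_replacement(self):
        rates = entry_exit_rates({2010: {"a", "b"}, 2011: {"b", "c"}})
        assert rates == {2011: (0.5, 0.5)}

    def test_year_gap_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            entry_exit_rates({2010: {"a"}, 2012: {"a"}})

    def test_growth_when_entries_exceed_exits(self):
        activity = {2010: {"a", "b"}, 2011: {"a", "b", "c"},
                    2012: {"a", "b", "c", "d"}}
        rates = entry_exit_rates(activity)
        assert all(entry > exit_ for entry, exit_ in rates.values())
        sizes = [len(activity[y]) for y in sorted(activity)]
        assert sizes == sorted(sizes)

    def test_yearly_activity_from_transactions(self, small_sim):
        activity = yearly_activity(small_sim.transactions)
        assert set(activity) == {2010}
        assert all(isinstance(v, set) for v in activity.values())


class TestYearToYearSimilarity:
    def test_identical_years_all_one(self):
        ms = _ms((("a", "b"), 1))
        res = year_to_year_similarity({2010: ms, 2011: ms, 2012: ms})
        assert list(res.series.values()) == [1.0, 1.0]
        assert res.median == res.minimum == res.maximum == 1.0

    def test_disjoint_years_all_zero(self):
        res = year_to_year_similarity(
            {2010: _ms((("a", "b"), 1)), 2011: _ms((("c", "d"), 1))}
        )
        assert list(res.series.values()) == [0.0]

    def test_half_turnover_approaches_one_third(self):
        """Keep each route with p=1/2 and add as many new ones: the expected
        unique Jaccard between consecutive years is 1/3."""
        rng = np.random.default_rng(7)
        n = 3000
        keys = {i: (f"m{i}", f"d{i}") for i in range(10 * n)}
        current = set(range(n))
        fresh = iter(range(n, 10 * n))
        by_year = {}
        for year in (2010, 2011, 2012):
            by_year[year] = PathMultiset([_p(*keys[k]) for k in current])
            kept = {k for k in current if rng.random() < 0.5}
            current = kept | {next(fresh) for _ in range(n - len(kept))}
        res = year_to_year_similarity(by_year)
        for value in res.series.values():
            assert value == pytest.approx(1 / 3, abs=0.05)
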