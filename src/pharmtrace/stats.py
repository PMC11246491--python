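"""Descriptive and validation statistics over distribution-path multisets.

Path identity throughout this module is the entity-ID sequence only; dates
and quantities are excluded, so the same route used on different days counts
as one path key with multiplicity.  This is what makes FIFO-vs-LIFO and
year-over-year comparisons meaningful: the routes can coincide even though
the shipping chronologies necessarily differ.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import DistributionPath

#: IUGG mean Earth radius, km — fixed for reproducible distance numbers
EARTH_RADIUS_KM = 6371.0088


class PathMultiset:
    """A collection of path records keyed by their entity sequence.

    Multiplicity of a key is the number of records carrying it (or,
    optionally, their summed quantities — see ``weight`` arguments below).
    """

    def __init__(self, records: Iterable[DistributionPath] = ()) -> None:
        self.records: list[DistributionPath] = list(records)

    def key_counts(self, weight: str = "count") -> Counter:
        """Multiplicities per canonical key.

        ``weight="count"`` counts records (the literal multiset reading);
        ``weight="quantity"`` sums delivered units instead.
        """
        if weight not in ("count", "quantity"):
            raise ValueError(f"unknown weight {weight!r}")
        counts: Counter = Counter()
        for r in self.records:
            counts[r.key] += 1 if weight == "count" else r.quantity
        return counts

    def keys(self) -> set[tuple[str, ...]]:
        return {r.key for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _as_multiset(x) -> PathMultiset:
    return x if isinstance(x, PathMultiset) else PathMultiset(x)


def jaccard_unique(a, b) -> float:
    """Jaccard similarity of the *sets* of unique path keys:
    ``|A ∩ B| / |A ∪ B|``.

    Symmetric, in [0, 1]; two empty sets are identical, so the result is
    defined as 1.
    """
    ka, kb = _as_multiset(a).keys(), _as_multiset(b).keys()
    union = ka | kb
    if not union:
        return 1.0
    return len(ka & kb) / len(union)


def jaccard_weighted(a, b, weight: str = "count") -> float:
    """Weighted Jaccard similarity accounting for path multiplicities:
    ``Σ_i min(a_i, b_i) / Σ_i max(a_i, b_i)`` over all keys i.

    Equals :func:`jaccard_unique` when every multiplicity is 0 or 1; two
    empty multisets give 1.
    """
    ca, cb = _as_multiset(a).key_counts(weight), _as_multiset(b).key_counts(weight)
    keys = set(ca) | set(cb)
    if not keys:
        return 1.0
    num = sum(min(ca.get(k, 0), cb.get(k, 0)) for k in keys)
    den = sum(max(ca.get(k, 0), cb.get(k, 0)) for k in keys)
    return num / den


def path_length_histogram(a) -> tuple[dict[int, int], float | None]:
    """Histogram of path lengths (number of distribution steps,
    ``len(path) - 1``) and the mean length.

    Counts sum to the number of records; the mean is None for an empty
    multiset.
    """
    ms = _as_multiset(a)
    hist: Counter = Counter(r.length for r in ms.records)
    if not ms.records:
        return {}, None
    mean = sum(r.length for r in ms.records) / len(ms.records)
    return dict(sorted(hist.items())), mean


def great_circle_km(
    p: tuple[float, float], q: tuple[float, float]
) -> float:
    """Haversine great-circle distance in km between two (lat, lon) points
    in degrees, on a sphere of radius 6371.0088 km."""
    for lat, lon in (p, q):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*p, *q))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (
        math.sin(dlat / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class ECCDF:
    """Empirical complementary CDF: ``P(X > x)`` — a nonincreasing,
    right-continuous step function over the sample."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    def __call__(self, x: float) -> float:
        if self.values.size == 0:
            raise ValueError("CCDF of an empty sample is undefined")
        return float(np.mean(self.values > x))

    def curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Support points and CCDF values just after each point (for plotting
        or CSV export)."""
        xs = np.unique(self.values)
        ps = np.array([self(x) for x in xs])
        return xs, ps


def ccdf(values: Sequence[float]) -> ECCDF:
    """Build an empirical complementary CDF from a sample."""
    return ECCDF(np.asarray(list(values), dtype=float))


@dataclass
class PathDistanceResult:
    """Geographic travel-distance summaries for a path multiset."""

    totals: list[float]  # per included path, km
    step_means: dict[int, float]  # step index (1-based) -> mean km
    total_ccdf: ECCDF | None
    n_skipped: int  # records with entities missing from the coordinate table

    def median_km(self) -> float | None:
        return float(np.median(self.totals)) if self.totals else None


def path_distances(
    a,
    coords: Mapping[str, tuple[float, float]],
) -> PathDistanceResult:
    """Total and per-step great-circle distances travelled along each path.

    Step 1 is the manufacturer → first-distributor hop.  The step-``k`` mean
    averages over paths having at least ``k`` steps.  Records visiting an
    entity absent from ``coords`` are skipped and counted.
    """
    ms = _as_multiset(a)
    totals: list[float] = []
    step_sums: Counter = Counter()
    step_counts: Counter = Counter()
    skipped = 0
    for r in ms.records:
        if any(e not in coords for e in r.path):
            skipped += 1
            continue
        total = 0.0
        for k, (u, v) in enumerate(zip(r.path, r.path[1:]), start=1):
            d = great_circle_km(coords[u], coords[v])
            total += d
            step_sums[k] += d
            step_counts[k] += 1
        totals.append(total)
    step_means = {k: step_sums[k] / step_counts[k] for k in sorted(step_counts)}
    return PathDistanceResult(
        totals=totals,
        step_means=step_means,
        total_ccdf=ccdf(totals) if totals else None,
        n_skipped=skipped,
    )


@dataclass
class TransitTimeResult:
    """Days-in-transit distribution (last shipping date − first)."""

    days: np.ndarray
    pdf: dict[int, float]
    days_ccdf: ECCDF | None

    def median(self) -> float | None:
        return float(np.median(self.days)) if self.days.size else None


def transit_time_distribution(a) -> TransitTimeResult:
    """Per-path days in transit with PDF and CCDF summaries.

    Transit time is the span between the first and last shipping dates of a
    path — a single-hop path has 0 days in transit by definition.
    """
    ms = _as_multiset(a)
    days = np.array([r.days_in_transit for r in ms.records], dtype=int)
    if days.size:
        counts = Counter(int(d) for d in days)
        n = days.size
        pdf = {k: counts[k] / n for k in sorted(counts)}
        return TransitTimeResult(days, pdf, ccdf(days))
    return TransitTimeResult(days, {}, None)


def entry_exit_rates(
    activity: Mapping[int, set],
) -> dict[int, tuple[float, float]]:
    """Per-year entry and exit rates of active entities.

    With ``A(t)`` the set of entities active in year ``t``:
    entry(t) = |A(t) \\ A(t−1)| / |A(t−1)| and
    exit(t) = |A(t−1) \\ A(t)| / |A(t−1)| — the standard turnover
    convention, normalising by the previous year's active set.  Years must
    be consecutive.
    """
    years = sorted(activity)
    if len(years) < 2:
        raise ValueError("need at least 2 consecutive years")
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise ValueError(f"years must be consecutive, got {years}")
    rates: dict[int, tuple[float, float]] = {}
    for prev, cur in zip(years, years[1:]):
        base = activity[prev]
        if not base:
            raise ValueError(f"no active entities in year {prev}")
        entered = len(activity[cur] - base)
        exited = len(base - activity[cur])
        rates[cur] = (entered / len(base), exited / len(base))
    return rates


def yearly_activity(transactions) -> dict[int, set]:
    """Entities active (as sender or receiver) per calendar year."""
    activity: dict[int, set] = {}
    for t in transactions:
        activity.setdefault(t.date.year, set()).update((t.sender_id, t.receiver_id))
    return activity


@dataclass
class YearSimilarityResult:
    """Year-to-year unique-Jaccard series with box-plot summary stats."""

    series: dict[tuple[int, int], float]
    minimum: float = field(init=False)
    q1: float = field(init=False)
    median: float = field(init=False)
    q3: float = field(init=False)
    maximum: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.array(list(self.series.values()))
        self.minimum = float(vals.min())
        self.q1 = float(np.percentile(vals, 25))
        self.median = float(np.median(vals))
        self.q3 = float(np.percentile(vals, 75))
        self.maximum = float(vals.max())


def year_to_year_similarity(
    paths_by_year: Mapping[int, PathMultiset],
) -> YearSimilarityResult:
    """Unique Jaccard similarity between consecutive years' path sets.

    A stable distribution system shows moderate, consistent similarity; a
    value near 0 signals an abrupt reorganisation of routes.
    """
    years = sorted(paths_by_year)
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    series = {
        (a, b): jaccard_unique(paths_by_year[a], paths_by_year[b])
        for a, b in zip(years, years[1:])
    }
    return YearSimilarityResult(series)
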