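"""Forward simulation of a multi-echelon drug-distribution process.

The simulator emits exactly the dyadic transaction stream a reporting system
would record for the simulated shipments, while keeping a ground-truth ledger
of every unit group's complete journey.  Because the ground truth is known,
the reconstruction engine can be tested end-to-end: replaying the stream
under the generating policy must recover the ledger's path multiset exactly.

The process emulated: manufacturers dispatch large batches to distributors
(Poisson-arriving, bounded random sizes); distributors hold batches in stock
for a random dwell, then repack and forward them — splitting across one or
more receivers — either deeper into the distribution tier or to a final
distributor (pharmacy, hospital, practitioner), which terminates the path.
Dispatch order from stock follows the configured FIFO/LIFO policy.

All randomness flows through one seeded generator in a fixed draw order that
never depends on the policy; stock *totals* evolve identically under FIFO
and LIFO, so two runs with the same seed and different policies produce
bit-identical transaction streams and differ only in the ground-truth paths.
That property is what :func:`perturb_policy` exploits for paired
FIFO-vs-LIFO comparisons.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .engine import Policy
from .records import DistributionPath, Entity, EntityType, Product, Transaction


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated distribution process.

    Defaults give a desk-scale system (a few thousand transactions over a
    quarter year) with the qualitative features of real pharmaceutical
    distribution: few manufacturers, an order of magnitude more distributors,
    many final distributors, short stock dwell and mostly short paths.
    """

    n_manufacturers: int = 3
    n_distributors: int = 12
    n_final_distributors: int = 50
    n_products: int = 2
    horizon_days: int = 120
    start_date: _dt.date = _dt.date(2010, 1, 1)
    #: mean manufacturer dispatches per manufacturer-day (Poisson)
    injection_rate: float = 0.4
    #: manufacturers inject only on days < injection_days (None: whole
    #: horizon); a drain phase lets aged stock finish its journey instead of
    #: being censored at the horizon
    injection_days: int | None = None
    #: inclusive bounds of the uniform integer batch size at injection
    batch_size_range: tuple[int, int] = (40, 400)
    policy: Policy = Policy.FIFO
    #: mean days a (distributor, product) stock waits between dispatches;
    #: realised as a daily dispatch probability 1 / (1 + mean_dwell_days)
    mean_dwell_days: float = 2.0
    #: fraction of current stock shipped per dispatch (uniform bounds)
    ship_fraction_range: tuple[float, float] = (0.25, 1.0)
    #: a dispatch splits among up to this many receivers
    max_receivers_per_dispatch: int = 2
    #: probability that a dispatch portion targets a final distributor
    terminal_prob: float = 0.4
    #: (lat_min, lat_max, lon_min, lon_max) for entity coordinates —
    #: default approximates the contiguous US
    bbox: tuple[float, float, float, float] = (24.5, 49.5, -124.5, -67.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_manufacturers", "n_distributors", "n_final_distributors",
                     "n_products", "horizon_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.injection_rate <= 0:
            raise ValueError("injection_rate must be positive")
        lo, hi = self.batch_size_range
        if not 1 <= lo <= hi:
            raise ValueError("batch_size_range must satisfy 1 <= lo <= hi")
        flo, fhi = self.ship_fraction_range
        if not 0 < flo <= fhi <= 1:
            raise ValueError("ship_fraction_range must satisfy 0 < lo <= hi <= 1")
        if not 0 <= self.terminal_prob <= 1:
            raise ValueError("terminal_prob must be in [0, 1]")
        if self.max_receivers_per_dispatch < 1:
            raise ValueError("max_receivers_per_dispatch must be >= 1")
        if self.mean_dwell_days < 0:
            raise ValueError("mean_dwell_days must be >= 0")
        if self.injection_days is not None and self.injection_days < 1:
            raise ValueError("injection_days must be >= 1 when given")


@dataclass
class GroundTruthLedger:
    """What actually happened: completed journeys and end-state stocks."""

    completed_paths: list[DistributionPath] = field(default_factory=list)
    residual_units: dict[tuple[str, str], int] = field(default_factory=dict)
    injected_units: int = 0

    def check_conservation(self) -> None:
        delivered = sum(p.quantity for p in self.completed_paths)
        residual = sum(self.residual_units.values())
        assert delivered + residual == self.injected_units, (
            f"ledger conservation violated: delivered {delivered} + residual "
            f"{residual} != injected {self.injected_units}"
        )


@dataclass
class SimulationResult:
    """A simulated scenario: the observable stream plus its hidden truth."""

    transactions: list[Transaction]
    entities: list[Entity]
    products: list[Product]
    ledger: GroundTruthLedger
    config: SimulationConfig | None = None

    @property
    def entity_map(self) -> dict[str, Entity]:
        return {e.dea_number: e for e in self.entities}

    @property
    def coordinates(self) -> dict[str, tuple[float, float]]:
        return {
            e.dea_number: (e.latitude, e.longitude)
            for e in self.entities
            if e.latitude is not None
        }


class _SimBatch:
    """Simulator-side batch: quantity plus its materialised journey so far.

    The simulator keeps fully materialised path lists (desk scale), in
    contrast to the engine's shared prefix nodes — deliberately independent
    bookkeeping so the round-trip test is a genuine cross-check.
    """

    __slots__ = ("quantity", "path", "dates")

    def __init__(self, quantity: int, path: list[str], dates: list[_dt.date]):
        self.quantity = quantity
        self.path = path
        self.dates = dates


def _draw(stock: list[_SimBatch], amount: int, policy: Policy):
    """Draw ``amount`` units in policy order; the stock must suffice."""
    allocations: list[tuple[_SimBatch, int]] = []
    remaining = amount
    while remaining > 0:
        batch = stock[0] if policy is Policy.FIFO else stock[-1]
        take = min(batch.quantity, remaining)
        allocations.append((batch, take))
        batch.quantity -= take
        remaining -= take
        if batch.quantity == 0:
            stock.pop(0 if policy is Policy.FIFO else -1)
    return allocations


def _make_entities(config: SimulationConfig, rng: np.random.Generator):
    ents: list[Entity] = []
    lat_min, lat_max, lon_min, lon_max = config.bbox
    final_kinds = ("Pharmacy", "Hospital", "Practitioner")

    def coords():
        return (
            float(rng.uniform(lat_min, lat_max)),
            float(rng.uniform(lon_min, lon_max)),
        )

    for i in range(config.n_manufacturers):
        lat, lon = coords()
        ents.append(Entity(f"M{i:04d}", "Manufacturer", f"City{i}", "XX",
                           f"{10000 + i:05d}", lat, lon))
    for i in range(config.n_distributors):
        lat, lon = coords()
        ents.append(Entity(f"D{i:04d}", "Distributor", f"City{100 + i}", "XX",
                           f"{20000 + i:05d}", lat, lon))
    for i in range(config.n_final_distributors):
        kind = final_kinds[int(rng.integers(0, len(final_kinds)))]
        lat, lon = coords()
        ents.append(Entity(f"F{i:05d}", kind, f"City{1000 + i}", "XX",
                           f"{30000 + i:05d}", lat, lon))
    return ents


def _make_products(config: SimulationConfig) -> list[Product]:
    ingredients = ("hydrocodone", "oxycodone", "fentanyl", "morphine",
                   "codeine", "methadone")
    products = []
    for j in range(config.n_products):
        labeler = f"{10001 + (j % max(1, config.n_manufacturers)):05d}"
        ndc = f"{labeler}{j:04d}01"
        products.append(Product.from_ndc(ndc, ingredients[j % len(ingredients)]))
    return products


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the distribution process and return the stream, the entity and
    product tables, and the ground-truth ledger.

    Deterministic under a fixed seed.  Transactions come out sorted by
    (date, emission order) with ``seq`` equal to the emission index, ready
    for the reconstruction engine.
    """
    rng = np.random.default_rng(config.seed)
    entities = _make_entities(config, rng)
    products = _make_products(config)
    manufacturers = [e.dea_number for e in entities
                     if e.entity_type is EntityType.MANUFACTURER]
    distributors = [e.dea_number for e in entities
                    if e.entity_type is EntityType.DISTRIBUTOR]
    finals = [e.dea_number for e in entities
              if e.entity_type is EntityType.FINAL_DISTRIBUTOR]

    stocks: dict[tuple[str, str], list[_SimBatch]] = {}
    ledger = GroundTruthLedger()
    transactions: list[Transaction] = []
    ship_prob = 1.0 / (1.0 + config.mean_dwell_days)
    lo, hi = config.batch_size_range

    def emit(date, sender, receiver, product, qty, stype, rtype):
        transactions.append(
            Transaction(date, sender, receiver, product, qty, stype, rtype,
                        seq=len(transactions))
        )

    for day in range(config.horizon_days):
        date = config.start_date + _dt.timedelta(days=day)

        # manufacturer injections
        injecting = (config.injection_days is None
                     or day < config.injection_days)
        for mi, m in enumerate(manufacturers) if injecting else ():
            for _ in range(int(rng.poisson(config.injection_rate))):
                product = products[int(rng.integers(0, len(products)))].ndc
                size = int(rng.integers(lo, hi + 1))
                recv = distributors[int(rng.integers(0, len(distributors)))]
                emit(date, m, recv, product, size,
                     EntityType.MANUFACTURER, EntityType.DISTRIBUTOR)
                stocks.setdefault((recv, product), []).append(
                    _SimBatch(size, [m, recv], [date])
                )
                ledger.injected_units += size

        # distributor forwarding — fixed iteration order; every random draw
        # below depends only on stock totals, which are policy-invariant
        for di, d in enumerate(distributors):
            for product in (p.ndc for p in products):
                stock = stocks.get((d, product))
                total = sum(b.quantity for b in stock) if stock else 0
                if total == 0 or rng.random() >= ship_prob:
                    continue
                frac = rng.uniform(*config.ship_fraction_range)
                amount = min(total, max(1, int(round(total * frac))))
                k = int(rng.integers(1, config.max_receivers_per_dispatch + 1))
                k = min(k, amount)
                # split amount into k positive parts at random cut points
                if k > 1:
                    cuts = np.sort(rng.choice(amount - 1, size=k - 1,
                                              replace=False) + 1)
                    parts = np.diff(np.concatenate(([0], cuts, [amount])))
                else:
                    parts = np.array([amount])
                for part in parts:
                    part = int(part)
                    if rng.random() < config.terminal_prob:
                        recv = finals[int(rng.integers(0, len(finals)))]
                        rtype = EntityType.FINAL_DISTRIBUTOR
                    else:
                        j = int(rng.integers(0, len(distributors) - 1)) \
                            if len(distributors) > 1 else di
                        if len(distributors) > 1 and j >= di:
                            j += 1
                        recv = distributors[j]
                        if recv == d:  # single-distributor system: deliver out
                            recv = finals[int(rng.integers(0, len(finals)))]
                            rtype = EntityType.FINAL_DISTRIBUTOR
                        else:
                            rtype = EntityType.DISTRIBUTOR
                    emit(date, d, recv, product, part,
                         EntityType.DISTRIBUTOR, rtype)
                    for src, qty in _draw(stock, part, config.policy):
                        if rtype is EntityType.FINAL_DISTRIBUTOR:
                            ledger.completed_paths.append(
                                DistributionPath(
                                    tuple(src.path + [recv]),
                                    tuple(src.dates + [date]),
                                    qty,
                                )
                            )
                        else:
                            stocks.setdefault((recv, product), []).append(
                                _SimBatch(qty, src.path + [recv],
                                          src.dates + [date])
                            )

    ledger.residual_units = {
        key: sum(b.quantity for b in stock)
        for key, stock in stocks.items()
        if sum(b.quantity for b in stock) > 0
    }
    return SimulationResult(transactions, entities, products, ledger, config)


def perturb_policy(
    config: SimulationConfig,
) -> tuple[SimulationResult, SimulationResult]:
    """Run the same demand realisation under FIFO and LIFO.

    Common random numbers: both runs share the seed and draw order, so the
    injections, dispatch amounts and routing are identical and only the
    batch dispatch order differs.  Returns (fifo_result, lifo_result); the
    two transaction streams are verified identical.
    """
    fifo = simulate(dataclasses.replace(config, policy=Policy.FIFO))
    lifo = simulate(dataclasses.replace(config, policy=Policy.LIFO))
    if fifo.transactions != lifo.transactions:
        raise AssertionError(
            "policy leaked into the transaction stream; draw order broken"
        )
    return fifo, lifo


def aging_stock_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scenario where stock accumulates and ages: heavy injections, long
    dwell, small dispatch fractions.  Under LIFO most packages leave quickly
    from the top of the pile while a tail of old stock lingers — the regime
    where FIFO and LIFO transit times separate."""
    params = dict(
        n_manufacturers=2,
        n_distributors=6,
        n_final_distributors=30,
        n_products=1,
        horizon_days=240,
        injection_rate=1.5,
        injection_days=120,
        batch_size_range=(50, 200),
        mean_dwell_days=4.0,
        ship_fraction_range=(0.1, 0.4),
        terminal_prob=0.5,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def shallow_stock_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scenario where stocks stay shallow: sparse injections, short dwell,
    near-complete dispatch fractions.  Most dispatches drain a single batch,
    so FIFO and LIFO mostly coincide — high weighted similarity with a
    smaller set of rare divergent routes."""
    params = dict(
        n_manufacturers=2,
        n_distributors=8,
        n_final_distributors=40,
        n_products=1,
        horizon_days=150,
        injection_rate=0.15,
        batch_size_range=(20, 80),
        mean_dwell_days=0.5,
        ship_fraction_range=(0.8, 1.0),
        terminal_prob=0.5,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def single_batch_limit_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scenario in the single-batch dispatch limit: every dispatch empties
    its stock into a single receiver (no dwell, whole-stock fractions), so
    dispatch order is immaterial and FIFO and LIFO yield identical path
    multisets."""
    params = dict(
        n_manufacturers=2,
        n_distributors=5,
        n_final_distributors=10,
        n_products=1,
        horizon_days=80,
        injection_rate=0.3,
        mean_dwell_days=0.0,
        ship_fraction_range=(1.0, 1.0),
        max_receivers_per_dispatch=1,
        terminal_prob=0.4,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


# ---------------------------------------------------------------------------
# Scripted scenarios (no randomness): textbook chronologies for the engine.
# ---------------------------------------------------------------------------

_EXAMPLE_NDC = "00001000150"


def _scripted_entities(spec: list[tuple[str, str]]) -> list[Entity]:
    return [Entity(eid, activity) for eid, activity in spec]


def worked_example() -> SimulationResult:
    """The canonical batch-splitting chronology.

    Day 0: manufacturer D0 ships a 10-unit batch to distributor D1.
    Day 1: D1 splits it — 2 units to D2 and 5 units to D3.
    Day 3: D2 and D3 each ship 1 unit to the pharmacy D4.

    Exactly two paths complete, (D0, D1, D2, D4) and (D0, D1, D3, D4), each
    of quantity 1 and length 3; D1 retains 3 units, D2 retains 1, D3
    retains 4 — partial paths still in transit.
    """
    t0 = _dt.date(2010, 1, 1)

    def day(n):
        return t0 + _dt.timedelta(days=n)

    entities = _scripted_entities(
        [("D0", "Manufacturer"), ("D1", "Distributor"), ("D2", "Distributor"),
         ("D3", "Distributor"), ("D4", "Pharmacy")]
    )
    M, D, F = (EntityType.MANUFACTURER, EntityType.DISTRIBUTOR,
               EntityType.FINAL_DISTRIBUTOR)
    ndc = _EXAMPLE_NDC
    rows = [
        (day(0), "D0", "D1", 10, M, D),
        (day(1), "D1", "D2", 2, D, D),
        (day(1), "D1", "D3", 5, D, D),
        (day(3), "D2", "D4", 1, D, F),
        (day(3), "D3", "D4", 1, D, F),
    ]
    transactions = [
        Transaction(dt, s, r, ndc, q, st, rt, seq=i)
        for i, (dt, s, r, q, st, rt) in enumerate(rows)
    ]
    ledger = GroundTruthLedger(
        completed_paths=[
            DistributionPath(("D0", "D1", "D2", "D4"),
                             (day(0), day(1), day(3)), 1),
            DistributionPath(("D0", "D1", "D3", "D4"),
                             (day(0), day(1), day(3)), 1),
        ],
        residual_units={("D1", ndc): 3, ("D2", ndc): 1, ("D3", ndc): 4},
        injected_units=10,
    )
    return SimulationResult(
        transactions, entities, [Product.from_ndc(ndc, "hydrocodone")], ledger
    )


def shortfall_example() -> SimulationResult:
    """The batch-combination chronology: an order larger than any one batch.

    Distributor D3 holds two batches — 4 units arrived first, then 2 units
    from a different manufacturer — and must ship 5 units to pharmacy D4.
    Under FIFO the 4 oldest units go first and 1 unit comes from the newer
    batch, yielding two paths with the same route shape but quantities 4
    and 1; one unit of the newer batch remains in stock.
    """
    t0 = _dt.date(2010, 1, 1)

    def day(n):
        return t0 + _dt.timedelta(days=n)

    entities = _scripted_entities(
        [("M0", "Manufacturer"), ("M1", "Manufacturer"),
         ("D3", "Distributor"), ("D4", "Pharmacy")]
    )
    M, D, F = (EntityType.MANUFACTURER, EntityType.DISTRIBUTOR,
               EntityType.FINAL_DISTRIBUTOR)
    ndc = _EXAMPLE_NDC
    rows = [
        (day(0), "M0", "D3", 4, M, D),
        (day(1), "M1", "D3", 2, M, D),
        (day(2), "D3", "D4", 5, D, F),
    ]
    transactions = [
        Transaction(dt, s, r, ndc, q, st, rt, seq=i)
        for i, (dt, s, r, q, st, rt) in enumerate(rows)
    ]
    ledger = GroundTruthLedger(
        completed_paths=[
            DistributionPath(("M0", "D3", "D4"), (day(0), day(2)), 4),
            DistributionPath(("M1", "D3", "D4"), (day(1), day(2)), 1),
        ],
        residual_units={("D3", ndc): 1},
        injected_units=6,
    )
    return SimulationResult(
        transactions, entities, [Product.from_ndc(ndc, "hydrocodone")], ledger
    )
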