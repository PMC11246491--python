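"""Chronological path reconstruction over per-(entity, product) batch stocks.

The engine replays a date-ordered transaction stream.  Every entity holds one
stock per product, an arrival-ordered queue of batches; each batch carries the
partial distribution path that brought it there.  A shipment draws the
required units from the sender's stock in policy order — FIFO dispatches the
oldest batches first, LIFO the newest — splitting batches as needed.  Each
drawn allocation becomes a new batch at the receiver with the path extended
by one hop, or, when the receiver is a final distributor (pharmacy, hospital,
practitioner), is emitted as a completed :class:`DistributionPath`.  Batches
still in stock when the stream ends are in transit and are never emitted.

Two bookkeeping rules keep unit counts conserved when the data are
incomplete:

* a manufacturer shipping more than its recorded inflow *injects* product —
  an origin batch whose path starts at the manufacturer;
* any other sender shipping more than its recorded inflow triggers an
  *exogenous* batch (unknown provenance, e.g. stock predating the observation
  window); every path descending from it is flagged ``exogenous_origin`` so
  unreliable paths can be filtered rather than silently mixed in.

Partial paths are stored as immutable shared prefix nodes (a reversed tree),
so splitting a batch shares its ancestry instead of copying it; paths are
materialised only on emission.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .records import DistributionPath, Entity, EntityType, Transaction

logger = logging.getLogger(__name__)


class UnknownEntityError(KeyError):
    """A transaction references an entity whose type cannot be resolved."""


class DateRegressionError(ValueError):
    """A shipping date precedes the last date already on the batch's path."""


class Policy(str, Enum):
    """Stock-management strategy: which batch fulfils an order first.

    FIFO dispatches the oldest batches first (the WHO-recommended practice
    for perishables and the primary assumption for drug distribution); LIFO
    dispatches the newest first.
    """

    FIFO = "fifo"
    LIFO = "lifo"


class PathNode:
    """One entity on a partial path, linking back to its shared prefix.

    Nodes are immutable and shared: when a batch splits, all children
    reference the same prefix chain, so memory grows with the number of
    distinct hops, not with the summed length of materialised paths.
    ``date`` is the shipping date of the hop *into* this entity (None at the
    path origin).
    """

    __slots__ = ("parent", "entity", "date")

    def __init__(
        self,
        parent: "PathNode | None",
        entity: str,
        date: _dt.date | None = None,
    ) -> None:
        self.parent = parent
        self.entity = entity
        self.date = date

    def last_date(self) -> _dt.date | None:
        node: PathNode | None = self
        while node is not None:
            if node.date is not None:
                return node.date
            node = node.parent
        return None

    def materialize(self) -> tuple[tuple[str, ...], tuple[_dt.date, ...]]:
        """Walk the prefix chain and return (entities, shipping dates)."""
        entities: list[str] = []
        dates: list[_dt.date] = []
        node: PathNode | None = self
        while node is not None:
            entities.append(node.entity)
            if node.date is not None:
                dates.append(node.date)
            node = node.parent
        entities.reverse()
        dates.reverse()
        return tuple(entities), tuple(dates)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        ents, _ = self.materialize()
        return f"PathNode({' -> '.join(ents)})"


def extend_path(
    prefix: PathNode,
    receiver_id: str,
    ship_date: _dt.date,
    on_regression: str = "warn",
) -> PathNode:
    """Return a new node extending ``prefix`` by one hop to ``receiver_id``.

    The new node references the old prefix; no ancestor is copied.  A
    shipping date earlier than the prefix's last date is a data correction:
    by default it is accepted with a warning (``on_regression="warn"``), or
    rejected with :class:`DateRegressionError` when ``on_regression="error"``.
    """
    last = prefix.last_date()
    if last is not None and ship_date < last:
        msg = (
            f"shipping date {ship_date} precedes last path date {last} "
            f"(extending to {receiver_id})"
        )
        if on_regression == "error":
            raise DateRegressionError(msg)
        logger.warning(msg)
    return PathNode(prefix, receiver_id, ship_date)


@dataclass
class Batch:
    """A quantity of one product in one entity's stock, with its partial path.

    ``arrival_key`` is ``(arrival date, creating-transaction seq)``; it
    totally orders batches for policy dispatch and is kept unchanged under
    partial consumption (age is arrival, not remaining size).
    """

    batch_id: int
    quantity: int
    node: PathNode
    arrival_key: tuple[_dt.date, int]
    exogenous: bool = False


class Stock:
    """Arrival-ordered batches of one product held by one entity.

    Batches are appended in chronological processing order, so the queue is
    already sorted by ``arrival_key``; FIFO draws from the front, LIFO from
    the back.
    """

    __slots__ = ("entity_id", "product_code", "batches")

    def __init__(self, entity_id: str, product_code: str) -> None:
        self.entity_id = entity_id
        self.product_code = product_code
        self.batches: deque[Batch] = deque()

    @property
    def total(self) -> int:
        return sum(b.quantity for b in self.batches)

    def append(self, batch: Batch) -> None:
        if self.batches and batch.arrival_key < self.batches[-1].arrival_key:
            raise ValueError("batch arrival_key regresses; stream not chronological")
        self.batches.append(batch)

    def __len__(self) -> int:
        return len(self.batches)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Stock({self.entity_id}, {self.product_code}, "
            f"{[(b.batch_id, b.quantity) for b in self.batches]})"
        )


def draw_allocations(
    stock: Stock,
    amount: int,
    policy: Policy,
    arrival_key: tuple[_dt.date, int] | None = None,
    shortfall_origin_is_exogenous: bool = True,
    _next_batch_id: Iterable[int] | None = None,
) -> tuple[list[tuple[Batch, int]], int]:
    """Draw ``amount`` units from ``stock`` in policy order.

    Returns ``(allocations, shortfall)`` where allocations are ``(batch,
    drawn quantity)`` pairs in dispatch order.  Fully consumed batches are
    removed; a partially consumed batch keeps its queue position and its
    original ``arrival_key``.  If the stock holds fewer than ``amount``
    units, the remainder is covered by a single freshly created batch whose
    path starts at the stocking entity — flagged exogenous (unknown
    provenance) unless ``shortfall_origin_is_exogenous`` is False, which
    marks a manufacturer injection.  ``arrival_key`` of the triggering
    transaction is required whenever a shortfall is possible.
    """
    if amount < 1:
        raise ValueError("amount must be >= 1")
    allocations: list[tuple[Batch, int]] = []
    remaining = amount
    while remaining > 0 and stock.batches:
        batch = stock.batches[0] if policy is Policy.FIFO else stock.batches[-1]
        take = min(batch.quantity, remaining)
        allocations.append((batch, take))
        batch.quantity -= take
        remaining -= take
        if batch.quantity == 0:
            if policy is Policy.FIFO:
                stock.batches.popleft()
            else:
                stock.batches.pop()
    shortfall = remaining
    if shortfall > 0:
        if arrival_key is None:
            raise ValueError("arrival_key required to cover a stock shortfall")
        bid = next(_next_batch_id) if _next_batch_id is not None else -1
        origin = Batch(
            batch_id=bid,
            quantity=0,  # fully consumed by this draw
            node=PathNode(None, stock.entity_id),
            arrival_key=arrival_key,
            exogenous=shortfall_origin_is_exogenous,
        )
        allocations.append((origin, shortfall))
    return allocations, shortfall


@dataclass
class Diagnostics:
    """Unit-conservation counters accumulated during reconstruction."""

    n_transactions: int = 0
    n_skipped_self_loops: int = 0
    n_skipped_unknown: int = 0
    n_exogenous_batches: int = 0
    exogenous_units: int = 0
    injected_units: int = 0
    delivered_units: int = 0
    units_received: dict = field(default_factory=dict)
    units_shipped: dict = field(default_factory=dict)


@dataclass
class ReconstructionResult:
    """Completed paths, end-of-stream stocks and conservation diagnostics.

    ``completed_products[i]`` is the NDC of ``completed_paths[i]`` — stocks
    are product-keyed, so every path belongs to exactly one product and the
    published per-NDC file layout is recoverable.
    """

    completed_paths: list[DistributionPath]
    completed_products: list[str]
    residual_stocks: dict[tuple[str, str], Stock]
    diagnostics: Diagnostics
    policy: Policy

    def paths_by_product(self) -> dict[str, list[DistributionPath]]:
        out: dict[str, list[DistributionPath]] = {}
        for path, ndc in zip(self.completed_paths, self.completed_products):
            out.setdefault(ndc, []).append(path)
        return out

    def residual_units(self) -> dict[tuple[str, str], int]:
        return {k: s.total for k, s in self.residual_stocks.items() if s.total > 0}

    def check_conservation(self) -> None:
        """Raise AssertionError if any unit-conservation law is violated.

        Per (entity, product): received − shipped == residual ≥ 0, where
        injected and exogenous batches count as received at creation.
        Globally: delivered + residual == injected + exogenous.
        """
        d = self.diagnostics
        residual = {k: s.total for k, s in self.residual_stocks.items()}
        keys = set(d.units_received) | set(d.units_shipped) | set(residual)
        for key in keys:
            rec = d.units_received.get(key, 0)
            shp = d.units_shipped.get(key, 0)
            res = residual.get(key, 0)
            assert rec - shp == res >= 0, (
                f"conservation violated at {key}: received {rec}, "
                f"shipped {shp}, residual {res}"
            )
        total_residual = sum(residual.values())
        assert (
            d.delivered_units + total_residual
            == d.injected_units + d.exogenous_units
        ), (
            f"global conservation violated: delivered {d.delivered_units} + "
            f"residual {total_residual} != injected {d.injected_units} + "
            f"exogenous {d.exogenous_units}"
        )


def _resolve_types(
    tx: Transaction, entity_types: Mapping[str, EntityType]
) -> tuple[EntityType | None, EntityType | None]:
    stype = tx.sender_type or entity_types.get(tx.sender_id)
    rtype = tx.receiver_type or entity_types.get(tx.receiver_id)
    return stype, rtype


class Reconstructor:
    """Streaming reconstruction: feed transactions in (date, seq) order, then
    :meth:`finalize`.

    ``entities`` may map entity id to :class:`Entity` or directly to
    :class:`EntityType`; it is only consulted for transactions that do not
    carry their own sender/receiver types.  ``on_unknown`` controls handling
    of unresolvable entity types ("skip" logs and skips the transaction,
    "error" raises); ``on_regression`` is passed to :func:`extend_path`.
    """

    def __init__(
        self,
        entities: Mapping[str, Entity] | Mapping[str, EntityType] | None = None,
        policy: Policy = Policy.FIFO,
        on_unknown: str = "skip",
        on_regression: str = "warn",
    ) -> None:
        self.policy = Policy(policy)
        self.on_unknown = on_unknown
        self.on_regression = on_regression
        self.entity_types: dict[str, EntityType] = {}
        if entities:
            for eid, ent in entities.items():
                self.entity_types[eid] = (
                    ent.entity_type if isinstance(ent, Entity) else EntityType(ent)
                )
        self.stocks: dict[tuple[str, str], Stock] = {}
        self.completed: list[DistributionPath] = []
        self.completed_products: list[str] = []
        self.diagnostics = Diagnostics()
        self._batch_counter = 0
        self._last_key: tuple[_dt.date, int] | None = None
        self._finalized = False

    def _next_batch_id(self) -> int:
        self._batch_counter += 1
        return self._batch_counter

    def _stock(self, entity_id: str, product_code: str) -> Stock:
        key = (entity_id, product_code)
        stock = self.stocks.get(key)
        if stock is None:
            stock = self.stocks[key] = Stock(entity_id, product_code)
        return stock

    def process(self, tx: Transaction) -> None:
        """Apply one transaction: draw from the sender, extend paths, stock or
        emit at the receiver."""
        if self._finalized:
            raise RuntimeError("reconstructor already finalized")
        d = self.diagnostics
        key = (tx.date, tx.seq)
        if self._last_key is not None and key < self._last_key:
            raise ValueError(
                f"transactions not sorted by (date, seq): {key} after {self._last_key}"
            )
        self._last_key = key

        if tx.sender_id == tx.receiver_id:
            d.n_skipped_self_loops += 1
            return
        stype, rtype = _resolve_types(tx, self.entity_types)
        if stype is None or rtype is None:
            if self.on_unknown == "error":
                missing = tx.sender_id if stype is None else tx.receiver_id
                raise UnknownEntityError(missing)
            d.n_skipped_unknown += 1
            logger.info("skipping transaction with unresolvable entity: %s", tx)
            return
        d.n_transactions += 1

        sender_stock = self._stock(tx.sender_id, tx.product_code)
        is_manufacturer = stype is EntityType.MANUFACTURER
        allocations, shortfall = draw_allocations(
            sender_stock,
            tx.quantity,
            self.policy,
            arrival_key=key,
            shortfall_origin_is_exogenous=not is_manufacturer,
            _next_batch_id=iter(lambda: self._next_batch_id(), None),
        )
        skey = (tx.sender_id, tx.product_code)
        if shortfall > 0:
            if is_manufacturer:
                d.injected_units += shortfall
            else:
                d.n_exogenous_batches += 1
                d.exogenous_units += shortfall
                logger.info(
                    "exogenous batch of %d units at %s (%s) on %s",
                    shortfall, tx.sender_id, tx.product_code, tx.date,
                )
            # injected/exogenous units count as received by the sender
            d.units_received[skey] = d.units_received.get(skey, 0) + shortfall
        d.units_shipped[skey] = d.units_shipped.get(skey, 0) + tx.quantity

        terminal = rtype is EntityType.FINAL_DISTRIBUTOR
        rkey = (tx.receiver_id, tx.product_code)
        for src, qty in allocations:
            node = extend_path(src.node, tx.receiver_id, tx.date, self.on_regression)
            if terminal:
                path, dates = node.materialize()
                self.completed.append(
                    DistributionPath(path, dates, qty, src.exogenous)
                )
                self.completed_products.append(tx.product_code)
                d.delivered_units += qty
            else:
                self._stock(tx.receiver_id, tx.product_code).append(
                    Batch(self._next_batch_id(), qty, node, key, src.exogenous)
                )
                d.units_received[rkey] = d.units_received.get(rkey, 0) + qty

    def finalize(self) -> ReconstructionResult:
        """Close the stream: completed paths are exactly the emissions to
        final distributors; stocked partial paths stay in transit."""
        self._finalized = True
        result = ReconstructionResult(
            completed_paths=self.completed,
            completed_products=self.completed_products,
            residual_stocks=self.stocks,
            diagnostics=self.diagnostics,
            policy=self.policy,
        )
        return result


def reconstruct(
    transactions: Iterable[Transaction],
    entities: Mapping[str, Entity] | Mapping[str, EntityType] | None = None,
    policy: Policy = Policy.FIFO,
    on_unknown: str = "skip",
    on_regression: str = "warn",
) -> ReconstructionResult:
    """Reconstruct distribution paths from a (date, seq)-ordered transaction
    stream under the given stock policy.

    Deterministic: identical inputs and policy give identical output.  See
    :class:`Reconstructor` for parameter semantics.
    """
    rec = Reconstructor(entities, policy, on_unknown, on_regression)
    for tx in transactions:
        rec.process(tx)
    return rec.finalize()
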