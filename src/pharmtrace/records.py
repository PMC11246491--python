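"""Domain types and I/O for transaction tables, entity/product tables and path records.

Input tables are plain CSV with a header row; column names are resolved
through a configurable ``schema_map`` because administrative extracts differ
in their exact headers.  Reconstructed paths are serialised as JSONL, one
object per line with keys ``path`` (the DEA-number sequence), ``dates``
(ISO-8601 shipping dates, one per distribution step) and ``quantity`` (units
delivered to the final distributor).
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path as _Path
from typing import Iterable, Mapping, Sequence, TextIO


class SchemaError(ValueError):
    """A mandatory column is missing or a table-level invariant is violated."""


class NdcFormatError(ValueError):
    """A product code is not an 11-digit NDC."""


class PathValidationError(ValueError):
    """A path record violates the DistributionPath invariants."""


class EntityType(str, Enum):
    """DEA business-activity classes collapsed to the three roles in a path.

    ``final_distributor`` is the umbrella for every entity that is neither a
    manufacturer nor a distributor (pharmacies, hospitals, practitioners,
    clinics) and terminates a distribution path.
    """

    MANUFACTURER = "manufacturer"
    DISTRIBUTOR = "distributor"
    FINAL_DISTRIBUTOR = "final_distributor"


#: substring patterns (lower-cased) used to map free-text business activities
MANUFACTURER_PATTERNS: tuple[str, ...] = ("manufact",)
DISTRIBUTOR_PATTERNS: tuple[str, ...] = ("distrib",)


def classify_activity(
    activity: str,
    manufacturer_patterns: Sequence[str] = MANUFACTURER_PATTERNS,
    distributor_patterns: Sequence[str] = DISTRIBUTOR_PATTERNS,
) -> EntityType:
    """Map a free-text business-activity string to an :class:`EntityType`.

    Anything matching no manufacturer/distributor pattern is a final
    distributor — the terminal role of a distribution path.
    """
    low = activity.strip().lower().replace("_", " ")
    if low in ("final distributor", "final-distributor"):
        return EntityType.FINAL_DISTRIBUTOR
    for pat in manufacturer_patterns:
        if pat in low:
            return EntityType.MANUFACTURER
    for pat in distributor_patterns:
        if pat in low:
            return EntityType.DISTRIBUTOR
    return EntityType.FINAL_DISTRIBUTOR


@dataclass(frozen=True)
class Transaction:
    """One dyadic shipment record: ``quantity`` units of ``product_code``
    shipped from ``sender_id`` to ``receiver_id`` on ``date``.

    ``seq`` is the input-order index assigned at load time; it makes
    within-date processing order deterministic (the data are daily, so no
    finer timestamp exists).
    """

    date: _dt.date
    sender_id: str
    receiver_id: str
    product_code: str
    quantity: int
    sender_type: EntityType | None = None
    receiver_type: EntityType | None = None
    seq: int = 0


@dataclass(frozen=True)
class Entity:
    """A DEA-registered entity (manufacturer, distributor or endpoint)."""

    dea_number: str
    business_activity: str
    city: str = ""
    state: str = ""
    zip: str = ""
    latitude: float | None = None
    longitude: float | None = None

    @property
    def entity_type(self) -> EntityType:
        return classify_activity(self.business_activity)

    @property
    def coordinates(self) -> tuple[float, float] | None:
        if self.latitude is None or self.longitude is None:
            return None
        return (self.latitude, self.longitude)


def parse_ndc(code: str) -> tuple[str, str, str]:
    """Split an 11-digit National Drug Code into its three positional parts.

    Returns ``(labeler_code, formulation_code, package_size_code)`` — the
    5-digit labeler/manufacturer, 4-digit formulation (active ingredient,
    dosage form, strength) and 2-digit package size.  Separators (hyphens,
    spaces) are stripped first.
    """
    digits = code.replace("-", "").replace(" ", "")
    if len(digits) != 11 or not digits.isdigit():
        raise NdcFormatError(
            f"NDC must be 11 digits (optionally hyphenated), got {code!r}"
        )
    return digits[:5], digits[5:9], digits[9:]


@dataclass(frozen=True)
class Product:
    """A drug product identified by its 11-digit NDC."""

    ndc: str
    labeler_code: str
    formulation_code: str
    package_size_code: str
    active_ingredient: str = ""

    @classmethod
    def from_ndc(cls, ndc: str, active_ingredient: str = "") -> "Product":
        lab, form, pkg = parse_ndc(ndc)
        return cls(lab + form + pkg, lab, form, pkg, active_ingredient)


@dataclass(frozen=True)
class DistributionPath:
    """A completed distribution path.

    ``path`` is the ordered entity sequence from the originating manufacturer
    to the final distributor; ``dates`` holds the shipping date of each
    distribution step, so ``len(dates) == len(path) - 1``; ``quantity`` is
    the number of units delivered along this path.  ``exogenous_origin``
    flags paths whose first entity is a synthetic origin created because the
    shipping entity's recorded stock was insufficient (e.g. stock predating
    the observation window); such paths are conserved but less reliable.
    """

    path: tuple[str, ...]
    dates: tuple[_dt.date, ...]
    quantity: int
    exogenous_origin: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", tuple(self.path))
        object.__setattr__(self, "dates", tuple(self.dates))

    @property
    def length(self) -> int:
        """Number of distribution steps (entities minus one)."""
        return len(self.path) - 1

    @property
    def key(self) -> tuple[str, ...]:
        """Canonical path identity: the entity sequence only."""
        return self.path

    @property
    def days_in_transit(self) -> int:
        return (self.dates[-1] - self.dates[0]).days

    def validate(self) -> None:
        if len(self.path) < 2:
            raise PathValidationError("path must contain at least 2 entities")
        if len(self.dates) != len(self.path) - 1:
            raise PathValidationError(
                f"need {len(self.path) - 1} dates for {len(self.path)} entities, "
                f"got {len(self.dates)}"
            )
        if any(b < a for a, b in zip(self.dates, self.dates[1:])):
            raise PathValidationError("dates must be nondecreasing")
        if self.quantity < 1:
            raise PathValidationError("quantity must be >= 1")


@dataclass
class RowError:
    """A malformed input row: collected, not fatal, unless strict mode is on."""

    line: int
    message: str


@dataclass
class LoadResult:
    """Transactions sorted by (date, input order), plus row-level errors."""

    transactions: list[Transaction]
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.transactions)

    def __len__(self) -> int:
        return len(self.transactions)


#: canonical transaction field -> default header (after normalisation)
DEFAULT_SCHEMA_MAP: dict[str, str] = {
    "date": "date",
    "sender_id": "sender",
    "receiver_id": "receiver",
    "product_code": "ndc",
    "quantity": "quantity",
    "sender_type": "sender_type",
    "receiver_type": "receiver_type",
}

_MANDATORY_FIELDS = ("date", "sender_id", "receiver_id", "quantity")


def _normalise_header(name: str) -> str:
    return name.strip().lower().replace(" ", "_")


def _as_text_stream(source, mode: str = "r"):
    """Accept a path or an open text stream; return (stream, needs_close)."""
    if isinstance(source, (str, _Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def load_transactions(
    source: str | _Path | TextIO,
    schema_map: Mapping[str, str] | None = None,
    date_format: str | None = None,
    strict: bool = False,
) -> LoadResult:
    """Read a transaction CSV and return records sorted by (date, input order).

    ``schema_map`` maps canonical field names (``date``, ``sender_id``,
    ``receiver_id``, ``product_code``, ``quantity``, ``sender_type``,
    ``receiver_type``) to the file's column headers; matching is
    case-insensitive and treats spaces as underscores, so Table-style headers
    like ``Sender Type`` resolve without configuration.  Dates parse as
    ISO-8601 unless ``date_format`` (a ``strptime`` format) is given.

    The sort is stable and keyed on the date only, so within-date input order
    is preserved; ``seq`` records the original input position.  Rows with an
    unparseable date or non-positive quantity are skipped and reported in
    ``LoadResult.errors`` (raised immediately when ``strict``).  A missing
    mandatory column raises :class:`SchemaError` naming the column.
    """
    smap = dict(DEFAULT_SCHEMA_MAP)
    if schema_map:
        smap.update(schema_map)

    stream, needs_close = _as_text_stream(source)
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise SchemaError("empty input: no header row")
        header_lookup = {_normalise_header(h): h for h in reader.fieldnames}

        columns: dict[str, str] = {}
        for fld, col in smap.items():
            actual = header_lookup.get(_normalise_header(col))
            if actual is None and fld in _MANDATORY_FIELDS:
                raise SchemaError(f"missing mandatory column {col!r} (field {fld})")
            if actual is not None:
                columns[fld] = actual

        transactions: list[Transaction] = []
        errors: list[RowError] = []
        for seq, row in enumerate(reader):
            line = seq + 2  # header is line 1
            try:
                raw_date = row[columns["date"]]
                if date_format:
                    date = _dt.datetime.strptime(raw_date.strip(), date_format).date()
                else:
                    date = _dt.date.fromisoformat(raw_date.strip())
                quantity = int(row[columns["quantity"]])
                if quantity < 1:
                    raise ValueError(f"non-positive quantity {quantity}")
                sender = row[columns["sender_id"]].strip()
                receiver = row[columns["receiver_id"]].strip()
                if not sender or not receiver:
                    raise ValueError("empty sender or receiver id")
                product = (
                    row[columns["product_code"]].strip()
                    if "product_code" in columns
                    else ""
                )
                stype = (
                    classify_activity(row[columns["sender_type"]])
                    if "sender_type" in columns and row[columns["sender_type"]]
                    else None
                )
                rtype = (
                    classify_activity(row[columns["receiver_type"]])
                    if "receiver_type" in columns and row[columns["receiver_type"]]
                    else None
                )
            except (KeyError, ValueError, TypeError) as exc:
                err = RowError(line, str(exc))
                if strict:
                    raise SchemaError(f"line {line}: {exc}") from exc
                errors.append(err)
                continue
            transactions.append(
                Transaction(date, sender, receiver, product, quantity, stype, rtype, seq)
            )

        transactions.sort(key=lambda t: t.date)  # stable: within-date order kept
        return LoadResult(transactions, errors)
    finally:
        if needs_close:
            stream.close()


def load_entities(source: str | _Path | TextIO) -> dict[str, Entity]:
    """Read an entities CSV keyed by DEA number.

    Expected columns: ``dea_number``, ``business_activity``, ``city``,
    ``state``, ``zip`` and optionally ``lat``/``lon`` (or
    ``latitude``/``longitude``).  Duplicate DEA numbers and out-of-range
    coordinates raise :class:`SchemaError`.
    """
    stream, needs_close = _as_text_stream(source)
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise SchemaError("empty input: no header row")
        cols = {_normalise_header(h): h for h in reader.fieldnames}
        for mandatory in ("dea_number", "business_activity"):
            if mandatory not in cols:
                raise SchemaError(f"missing mandatory column {mandatory!r}")

        def get(row, *names, default=""):
            for n in names:
                if n in cols and row[cols[n]] not in (None, ""):
                    return row[cols[n]]
            return default

        entities: dict[str, Entity] = {}
        for row in reader:
            dea = row[cols["dea_number"]].strip()
            if dea in entities:
                raise SchemaError(f"duplicate DEA number {dea!r}")
            lat = get(row, "lat", "latitude", default=None)
            lon = get(row, "lon", "longitude", default=None)
            lat = float(lat) if lat is not None else None
            lon = float(lon) if lon is not None else None
            if lat is not None and not -90.0 <= lat <= 90.0:
                raise SchemaError(f"latitude out of range for {dea!r}: {lat}")
            if lon is not None and not -180.0 <= lon <= 180.0:
                raise SchemaError(f"longitude out of range for {dea!r}: {lon}")
            entities[dea] = Entity(
                dea_number=dea,
                business_activity=row[cols["business_activity"]].strip(),
                city=get(row, "city"),
                state=get(row, "state"),
                zip=get(row, "zip", "zip_code"),
                latitude=lat,
                longitude=lon,
            )
        return entities
    finally:
        if needs_close:
            stream.close()


def load_products(source: str | _Path | TextIO) -> dict[str, Product]:
    """Read a products CSV (``ndc``, ``active_ingredient``) keyed by NDC."""
    stream, needs_close = _as_text_stream(source)
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise SchemaError("empty input: no header row")
        cols = {_normalise_header(h): h for h in reader.fieldnames}
        if "ndc" not in cols:
            raise SchemaError("missing mandatory column 'ndc'")
        products: dict[str, Product] = {}
        for row in reader:
            prod = Product.from_ndc(
                row[cols["ndc"]],
                row[cols["active_ingredient"]].strip()
                if "active_ingredient" in cols
                else "",
            )
            products[prod.ndc] = prod
        return products
    finally:
        if needs_close:
            stream.close()


def write_paths_jsonl(
    paths: Iterable[DistributionPath], sink: str | _Path | TextIO
) -> int:
    """Write path records as JSONL; returns the number of lines written.

    Field order is fixed (``path``, ``dates``, ``quantity``) for diff-stable
    output; ``exogenous_origin`` is emitted only when true.  Every record is
    validated first; a violating record raises :class:`PathValidationError`
    naming its index.
    """
    stream, needs_close = _as_text_stream(sink, "w")
    try:
        n = 0
        for i, p in enumerate(paths):
            try:
                p.validate()
            except PathValidationError as exc:
                raise PathValidationError(f"record {i}: {exc}") from exc
            obj: dict = {
                "path": list(p.path),
                "dates": [d.isoformat() for d in p.dates],
                "quantity": p.quantity,
            }
            if p.exogenous_origin:
                obj["exogenous_origin"] = True
            stream.write(json.dumps(obj, separators=(", ", ": ")))
            stream.write("\n")
            n += 1
        return n
    finally:
        if needs_close:
            stream.close()


def read_paths_jsonl(source: str | _Path | TextIO) -> list[DistributionPath]:
    """Read JSONL path records; inverse of :func:`write_paths_jsonl`.

    Blank lines are skipped; unknown keys are ignored; a malformed line or a
    line missing a required key raises :class:`ValueError` with its line
    number.
    """
    stream, needs_close = _as_text_stream(source)
    try:
        out: list[DistributionPath] = []
        for lineno, line in enumerate(stream, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            try:
                path = tuple(obj["path"])
                dates = tuple(_dt.date.fromisoformat(d) for d in obj["dates"])
                quantity = int(obj["quantity"])
            except KeyError as exc:
                raise ValueError(f"line {lineno}: missing key {exc.args[0]!r}") from exc
            out.append(
                DistributionPath(
                    path, dates, quantity, bool(obj.get("exogenous_origin", False))
                )
            )
        return out
    finally:
        if needs_close:
            stream.close()


def write_transactions_csv(
    transactions: Iterable[Transaction], sink: str | _Path | TextIO
) -> int:
    """Write transactions in the canonical CSV dialect `load_transactions` reads."""
    stream, needs_close = _as_text_stream(sink, "w")
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(
            ["date", "sender", "receiver", "ndc", "quantity", "sender_type",
             "receiver_type"]
        )
        n = 0
        for t in transactions:
            writer.writerow(
                [
                    t.date.isoformat(),
                    t.sender_id,
                    t.receiver_id,
                    t.product_code,
                    t.quantity,
                    t.sender_type.value if t.sender_type else "",
                    t.receiver_type.value if t.receiver_type else "",
                ]
            )
            n += 1
        return n
    finally:
        if needs_close:
            stream.close()


def write_entities_csv(
    entities: Iterable[Entity], sink: str | _Path | TextIO
) -> int:
    """Write an entities table in the dialect `load_entities` reads."""
    stream, needs_close = _as_text_stream(sink, "w")
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(
            ["dea_number", "business_activity", "city", "state", "zip", "lat", "lon"]
        )
        n = 0
        for e in entities:
            writer.writerow(
                [
                    e.dea_number,
                    e.business_activity,
                    e.city,
                    e.state,
                    e.zip,
                    "" if e.latitude is None else repr(e.latitude),
                    "" if e.longitude is None else repr(e.longitude),
                ]
            )
            n += 1
        return n
    finally:
        if needs_close:
            stream.close()
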