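# Methods

## The reconstruction procedure

The input is a chronological stream of dyadic shipping transactions
(date, sender, receiver, product, quantity), daily resolution. The engine
maintains one stock per (entity, product): a queue of batches ordered by
arrival key `(arrival date, creating-transaction index)`. Each batch carries
its partial path as a reference into an immutable prefix tree — splitting a
batch shares ancestry rather than copying it, so memory is proportional to
the number of hops processed, not to the summed length of all paths. Paths
are materialised only when emitted.

For a transaction of quantity *q* the sender's stock is drawn in policy
order (FIFO: ascending arrival key; LIFO: descending), combining batches
when *q* exceeds the front batch and leaving a partially drawn batch in
place with its original arrival key (a batch's age is its arrival, not its
remaining size). Each allocation becomes a batch at the receiver, or a
completed path when the receiver is a final distributor. End-of-stream
stocks are "in transit" and never emitted.

### Assumptions

* **The stock policy is the single degree of freedom.** Timing and
  quantities are fully determined by the data; only which batch fulfils an
  order is assumed (FIFO by default — standard practice for perishables).
* **Daily resolution, stable order.** Same-day transactions are processed
  in input order; ties among same-day arrivals are broken by the creating
  transaction's index. This makes the reconstruction fully deterministic.
* **Final distributors are terminals.** Any entity that is neither a
  manufacturer nor a distributor ends a path; its received units are never
  re-shipped. If dirty data nevertheless shows such an entity shipping, the
  shipment is served by an exogenous batch and logged.
* **Per-product isolation.** Stocks are keyed by NDC; units of different
  products never mix.

### Incomplete data and conservation

Senders can ship more than their recorded inflow (initial stocks predating
the data window; missing records). The engine never drops those units:

* a **manufacturer** shortfall is an *injection* — a fresh origin batch whose
  path starts at the manufacturer (this is also how every ordinary
  manufacturer shipment starts, since manufacturers have no recorded
  inflow);
* any **other** sender's shortfall creates an *exogenous* batch whose path
  starts at that sender, and every descendant path is flagged
  `exogenous_origin` so downstream analyses can filter unreliable paths
  instead of silently mixing them.

With these rules the accounting identities hold exactly and are checked by
`ReconstructionResult.check_conservation()`: per (entity, product),
received − shipped = residual ≥ 0; globally, delivered + residual =
injected + exogenous.

Other deliberate choices: self-loop transactions (sender = receiver) carry
no path information and are skipped and counted; cycles across *distinct*
entities are recorded as-is; a shipping date earlier than a batch's last
path date (administrative corrections) is accepted with a warning by
default, or rejected in strict mode.

## Statistics

* **Path identity** for all similarity comparisons is the entity-ID sequence
  only. Dates and quantities are excluded because the comparisons of
  interest (FIFO vs LIFO, year vs year) pair streams whose chronologies
  necessarily differ; including dates would push every similarity towards
  zero and measure nothing about routing.
* **Weighted Jaccard multiplicity** defaults to record counts (the literal
  multiset reading); quantity-weighted multiplicities are available via
  `weight="quantity"`.
* **Jaccard of two empty collections** is defined as 1 (identical inputs),
  keeping the identity property exact.
* **Distances** use the haversine formula on a sphere of radius
  6371.0088 km (IUGG mean radius) — fixed so distance outputs are
  reproducible to the last digit. Step 1 of the per-step means is the
  manufacturer → first-distributor hop.
* **Entry/exit rates** normalise by the previous year's active set:
  entry(t) = |A(t)∖A(t−1)|/|A(t−1)|, exit(t) = |A(t−1)∖A(t)|/|A(t−1)| —
  the standard turnover convention; callers choose the entity subset (all
  entities, or mid-chain distributors only).
* **Days in transit** is last minus first shipping date; a single-hop path
  is 0 days by definition.
* Empirical CCDFs are right-continuous step functions `P(X > x)`; an empty
  sample has no CCDF (error), and histogram/CCDF mass is always conserved.

## The synthetic generator

`pharmtrace.simulate` forward-simulates a multi-echelon process:
manufacturers dispatch batches to distributors (Poisson arrivals per
manufacturer-day, uniform bounded sizes); each (distributor, product) stock
dispatches on a given day with probability 1/(1 + mean dwell), shipping a
uniform fraction of its stock split across up to `max_receivers_per_dispatch`
receivers, each portion going to a final distributor with probability
`terminal_prob`. Dispatch draws follow the configured policy with exactly
the engine's semantics, but the simulator's bookkeeping (materialised path
lists, plain queues) is implemented independently, so the
ledger-vs-reconstruction round trip is a genuine cross-check, not a tautology.

Defaults (3 manufacturers, 12 distributors, 50 final distributors, 2
products, 120 days, injection rate 0.4/manufacturer-day, batch sizes
40–400, mean dwell 2 days, dispatch fractions 0.25–1.0, terminal
probability 0.4, coordinates uniform over a contiguous-US bounding box)
give a few thousand transactions and ~1,000 completed paths in well under a
second — sized so the full test suite and scenario sweeps run in seconds.
The ratios mirror the qualitative shape of real pharmaceutical registries:
manufacturers ≪ distributors ≪ endpoints, short dwells, mostly short paths.

All randomness flows through one seeded generator in a draw order that
depends only on stock *totals*, which are policy-invariant; hence
`perturb_policy` can run FIFO and LIFO on bit-identical transaction streams
(common random numbers) and compare paired outcomes.

Named scenario families:

* `aging_stock_config` — heavy injections, long dwell, small dispatch
  fractions, and a drain phase (injections stop halfway through the
  horizon). The drain phase matters: without it, LIFO's oldest stock never
  ships before the stream ends, and the finite sample censors exactly the
  right tail the comparison is about. With it, the qualitative FIFO/LIFO
  signature (LIFO median transit ≤ FIFO's, with LIFO's transit CCDF
  crossing above FIFO's in the tail) holds on every seed tested.
* `shallow_stock_config` — sparse injections, near-complete dispatches;
  stocks rarely hold more than a couple of batches.
* `single_batch_limit_config` — every dispatch empties its stock into a
  single receiver, so dispatch order is immaterial and FIFO ≡ LIFO exactly
  (both Jaccard indices are 1); this limit is asserted in the tests.

### What the generator does not emulate

The simulator is not calibrated to any real market: no real volumes,
geography, market shares or seasonality, no shipment-level reporting noise,
and no double-entry (purchase-side) records. Consequently, passing tests
demonstrate the *correctness* of the reconstruction and statistics under a
known process, not the realism of any particular statistic's value on real
data. One concrete instance: on real data the weighted path similarity
between FIFO and LIFO reconstructions is far higher than the unique
similarity, because real multiplicity concentrates on policy-invariant
high-volume routes. Desk-scale synthetic streams do not reproduce that
concentration (weighted ≈ unique here, with no stable ordering between the
two), so no weighted-vs-unique ordering is asserted; the policy-contrast
tests assert the transit-time signature and the single-batch limit instead.

## Numerical and format choices

* Dates are ISO-8601 in all formats, with a configurable `strptime` format
  on input; JSONL field order is fixed (`path`, `dates`, `quantity`) so
  identical inputs give byte-identical outputs.
* CSV loading is permissive by default (malformed rows collected and
  reported, not fatal) because large administrative extracts contain dirt;
  `strict` makes any malformed row fatal.
* Business activities map to the three roles by substring patterns
  ("manufact", "distrib"); everything else is a final distributor, matching
  the umbrella definition.
* Problem sizes in the test suite: round-trip oracles run 20 scenario
  configurations of ≤ ~2,500 transactions each; statistics oracles use a
  few hundred random comparisons. These sizes make every suite complete in
  seconds while leaving all code paths (splitting, combination, multi-product,
  both policies, all scenario families) exercised.

## Known limitations

* Production-scale streams (10⁸ transactions) would need out-of-core
  processing and a compact arena for path nodes; the current engine is
  in-memory, though the shared-prefix contract is the right asymptotic
  design.
* Geocoding is out of scope: distance statistics require caller-supplied
  coordinates per entity.
* Early-window paths in real extracts inherit unknown initial stock; they
  appear here as exogenous-flagged paths and should be filtered for
  sensitive analyses.
* The engine trusts the declared entity typing; a mistyped final
  distributor would truncate paths at that entity.
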