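# pharmtrace

Reconstruct complete per-package **distribution paths** — manufacturer →
distributors → final destination — from dyadic pharmaceutical shipping
records, and validate the reconstruction.

Regulatory shipping databases such as the DEA's ARCOS record every legal
shipment of a controlled substance as a *dyadic* transaction: one sender, one
receiver, a date, an 11-digit NDC product code and a quantity. What they do
not record is the journey of a package through the chain: which manufacturer
batch a pharmacy's delivery actually came from. `pharmtrace` recovers those
journeys for researchers studying distribution networks (resilience,
recalls, anomalous routing), by replaying the transaction stream
chronologically against per-(entity, product) stocks.

## The reconstruction model

Each manufacturer or distributor *i* holds a stock per product: an
arrival-ordered queue of batches, every batch carrying the partial path that
brought it there. Processing a transaction (t, i → j, q):

1. draw *q* units from *i*'s stock in **policy order** — FIFO dispatches the
   oldest batches first (the WHO-recommended practice for perishables, and
   the default assumption), LIFO the newest — splitting batches when an
   order straddles them;
2. extend each drawn allocation's path by *j* with shipping date *t*;
3. if *j* is a **final distributor** (pharmacy, hospital, practitioner — any
   entity that is neither manufacturer nor distributor), emit the allocation
   as a completed path `(path, dates, quantity)`; otherwise it becomes a new
   batch in *j*'s stock.

Batches still in stock at the end of the stream are in transit and never
emitted. A sender shipping more than its recorded inflow either *injects*
product (manufacturers) or triggers a flagged *exogenous* batch (unknown
provenance, e.g. stock predating the data window), so unit conservation
holds exactly: delivered + residual = injected + exogenous.

Validation statistics compare path multisets by their entity sequences:
unique Jaccard J(A,B) = |A∩B| / |A∪B|, weighted Jaccard
Σᵢ min(aᵢ,bᵢ) / Σᵢ max(aᵢ,bᵢ) over path multiplicities, path-length
histograms, haversine travel distances, days-in-transit distributions and
distributor entry/exit rates.

A forward simulator (`pharmtrace.simulate`) generates multi-echelon
distribution processes with known ground-truth paths, so reconstruction can
be verified to recover the truth *exactly* on synthetic streams.

## Worked example

The canonical chronology: on day 0 manufacturer D0 ships a 10-unit batch to
distributor D1; on day 1 D1 splits it, sending 2 units to D2 and 5 to D3;
on day 3 D2 and D3 each ship 1 unit to the pharmacy D4.

```python
from pharmtrace import Policy, reconstruct, worked_example

scenario = worked_example()
result = reconstruct(scenario.transactions, policy=Policy.FIFO)
for p in result.completed_paths:
    print(p.path, p.quantity, p.length)
print(result.residual_units())
```

prints

```
('D0', 'D1', 'D2', 'D4') 1 3
('D0', 'D1', 'D3', 'D4') 1 3
{('D1', '00001000150'): 3, ('D2', '00001000150'): 1, ('D3', '00001000150'): 4}
```

Exactly two paths complete — each of length 3 (three distribution steps),
each delivering 1 unit — while 8 of the 10 injected units remain in transit:
3 at D1, 1 at D2, 4 at D3.

## Command line

```sh
pharmtrace simulate    --out-dir sim --seed 7 --horizon-days 90
pharmtrace reconstruct --transactions sim/transactions.csv \
                       --entities sim/entities.csv --policy fifo --out-dir rec
pharmtrace validate    --transactions sim/transactions.csv --out report.json
pharmtrace stats       --paths rec/paths_*.jsonl --entities sim/entities.csv \
                       --out-dir stats
```

`reconstruct` writes one JSONL file per NDC plus a diagnostics summary, e.g.

```json
{
  "paths_emitted": 865,
  "injected_units": 26333,
  "delivered_units": 23003,
  "residual_units": 3330,
  "exogenous_batches": 0,
  ...
}
```

and `validate` reconstructs the same stream under both FIFO and LIFO and
reports their unique/weighted Jaccard similarity and transit-time medians.
Exit codes: 0 success, 1 usage error, 2 data-validation failure.

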