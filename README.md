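# digilabor

Experience-aware labor estimation for natural-history collection
digitization.

Digitizing a herbarium — applying barcode stickers, photographing
sheets, transcribing skeletal label data — is dominated by labor cost,
and most of that labor comes from inexperienced student technicians who
get faster as they practice. A project's labor budget therefore depends
not just on how many specimens there are, but on how long each
technician stays: high turnover keeps everyone on the slow end of the
learning curve. `digilabor` turns raw technician session logs into
labor forecasts that account for this.

The package covers the full analysis chain:

1. **Synthetic session logs** (`digilabor.simulate`) — generate
   work-session report tables (reporter, date, task, minutes, specimens,
   free-text setback field) with configurable anomaly injection and
   ground-truth labels, so every downstream stage is testable without
   any project's raw data.
2. **Cleaning** (`digilabor.cleaning`) — a five-stage exclusion
   procedure with full audit accounting: manually flagged reporters,
   atypical-workflow entries, swapped-field entry errors, non-whitelisted
   setback descriptions, and 5-SD numeric outliers.
3. **Experience curves** (`digilabor.experience`) — per-technician
   cumulative task hours, shared two-hour experience bins below a
   64-hour threshold, and least-squares fits of mean bin rate *y*
   (specimens/minute, SPM) against cumulative hours *x*:

   * imaging: *y* = 1.95170 + 0.02118 *x* (capped at 4.00 SPM)
   * skeletal databasing: *y* = 2.55659 + 0.02760 *x* (capped at 6.50 SPM)
   * barcoding: *y* = 3.7216 + 0.09928 *x* − 0.00175 *x*² (floored at 3.00 SPM)

4. **Turnover labor projection** (`digilabor.projection`) — a
   discrete-hour simulator in which a technician's hourly output follows
   their task curve, experience freezes one hour past the 64-hour model
   boundary, and every `contract_duration` hours the technician is
   replaced by a novice (rate resets, production carries over). The
   default grid — contract durations {15, 30, 45, 60, 90, 135} hours ×
   thirteen specimen counts from 10,000 to 500,000 — produces the full
   reference labor-projection table for the three tasks plus their
   combined total.
5. **Productivity reports** (`digilabor.productivity`) — project-wide
   rates under three hour-accounting conventions, per-task rates,
   setback incidence/duration summaries and setback word frequencies.

A thin CLI (`digilabor run|simulate-sessions|clean|fit|project|report`)
chains the stages; `examples/` contains one narrative script per
capability.

## Worked example

```python
from digilabor import projection_table, retention_savings

table = projection_table(durations=[15, 135], counts=[10_000, 500_000])
print(table)
print(retention_savings(table, 500_000))
```

```
specimen_count                         10000   500000
contract_duration task
15                barcoding                39     1907
                  imaging                  79     3929
                  skeletal_databasing      61     3001
                  combined                179     8837
135               barcoding                35     2233
                  imaging                  64     2782
                  skeletal_databasing      51     2127
                  combined                150     7142
0.1918072196446533
```

Reading it: digitizing 500,000 specimens end-to-end with 15-hour
technician contracts takes 8,837 labor hours; with 135-hour contracts it
takes 7,142 — longer retention saves 19.2% of the labor, even though
barcoding alone gets *slower* with long retention (its rate curve peaks
near 28 hours and declines, so barcoding hours rise from 1,907 to 2,233
while the two improving tasks more than compensate).

The full pipeline on synthetic data:

```sh
digilabor run --seed 11 --out-dir out/
```

writes sessions, labels, the cleaning audit, experience bins, fitted
models, the projection table and a productivity report, e.g.:

```
Project-wide rates (specimens/minute):
  method A (pre-clean specimens / pre-clean hours):   0.664
  method B (post-clean specimens / post-clean hours): 0.723
  method C (post-clean specimens / primary hours):    1.074
```

(the three methods differ in which specimens and hours count toward the
rate; see `docs/methods.md`).

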