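# masslink

Reconciliation of U.S. mass-shooting incident databases.

No two major U.S. mass-shooting databases agree on what a mass shooting is.
The FBI's Supplementary Homicide Report (SHR, subset to single-shooter
incidents with ≥4 firearm fatalities), the FBI Active Shooter Report (ASR, no
victim threshold but motive exclusions), Mother Jones (MJ, ≥3 killed, one
identified shooter, "indiscriminate" only), Everytown for Gun Safety (≥4
killed, any motive) and Gun Violence Archive (GVA, ≥4 killed **or** injured)
each apply a different case definition, so they list substantially different
incident populations for the same years (2013–2020). Quantifying how
different — how many discrete incidents exist across all five lists, and how
few appear in every list — requires harmonizing the exports, linking the
*imperfect duplicates* (same incident, slightly different date, city
spelling, or casualty count), and counting exclusive set overlaps.

`masslink` is that pipeline, for epidemiologists and policy researchers
working with multi-source injury surveillance data:

- **readers** — per-source CSV dialects, strict date parsing with a
  structured error report, victim-level SHR grouping and the SHR
  mass-killing subset, study-window filtering, state/city harmonization;
- **definitions** — each database's inclusion criteria as declarative,
  evaluable `Definition` objects, plus threshold re-filtering and the
  per-source filter ledger (excluded = total − surviving);
- **linkage** — blocking (same state, dates within ±1 day), field-wise
  similarity scoring, MATCH/REVIEW/NONMATCH classification with an
  exportable manual-review queue, and transitive-closure clustering:
  each resulting cluster is one real-world incident;
- **overlap** — the boolean incidents × sources membership matrix,
  exclusive (UpSet-convention) intersection counts, per-source summary
  tables and UpSet-format exports;
- **synthetic** — a generator that draws a ground-truth incident universe
  and emits the five source exports under each database's criteria with
  imperfect detection and field perturbations, so every stage is testable
  against known truth.

## The core statistic

For record pair $(a, b)$ from different sources, the match score is a
weighted mean over the similarity components present on both sides,

$$s(a,b) = \frac{\sum_k w_k\, \mathrm{sim}_k(a,b)}{\sum_k w_k},
\qquad \mathrm{sim}_k \in [0,1],$$

with default weights date 0.25, state 0.20, city 0.20, shooter name 0.15,
killed 0.10, injured 0.10. City and name similarities are normalized
edit-distance similarities ($1 - d/\max(|x|,|y|)$); count similarities are
$1 - |\Delta|/\max(a,b,1)$. Pairs with $s \ge 0.90$ link automatically,
$0.70 \le s < 0.90$ go to the review queue, and incidents are the connected
components of the link graph. Given clusters $C$ and source set $S$, the
UpSet analysis reports exclusive counts
$n_T = |\{c \in C : \mathrm{sources}(c) = T\}|$ for each $T \subseteq S$,
which partition the union: $\sum_T n_T = |C|$.

## Worked example

Generate a synthetic five-database bundle (500 true incidents, default 95%
detection and 5% per-field perturbation rates) and run the full pipeline:

```sh
masslink generate --n 500 --seed 17 --out-dir demo/data
masslink run --in-dir demo/data --out-dir demo/report
```

which prints

```
SHR: 93 incidents
ASR: 175 incidents
MJ: 61 incidents
EVERYTOWN: 97 incidents
GVA: 295 incidents
union 370 incidents; all-source overlap 26; >=4-fatality union 104
```

Reading: the five simulated databases list 93–295 incidents each (GVA the
most — its threshold counts injuries; MJ among the fewest — its criteria are
strictest), but after cross-source linkage they describe only 370 discrete
incidents, of which just 26 appear in all five lists. Re-filtering every
source at the most conservative definition (≥4 fatalities) shrinks the union
to 104. `demo/report/` contains the per-source summary
(`source_summary.csv`), the cluster file, the review queue for manual
adjudication, parse errors, the three UpSet-format overlap tables
(`overlap_all.csv`, `overlap_excl_gva.csv`, `overlap_min4.csv`) and
`report.json` with the headline counts; e.g. the first rows of
`overlap_all.csv`:

```
SHR,ASR,MJ,EVERYTOWN,GVA,count
False,False,False,False,True,124
False,True,False,False,False,69
False,True,False,False,True,57
```

124 incidents are listed *only* by GVA, 69 only by ASR, and so on.

As a library:

```python
from masslink import PRESETS, evaluate, SourceRecord, Source
record = SourceRecord("x1", Source.GVA, None, "TX", "Houston",
                      n_shooters=1, killed_excl_perp=0, injured_excl_perp=4)
evaluate(record, PRESETS["GVA"]).eligible        # True  (4 casualties)
evaluate(record, PRESETS["EVERYTOWN"]).eligible  # False (0 fatalities)
```

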