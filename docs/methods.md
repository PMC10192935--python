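# Methods

## Problem and approach

Five widely used U.S. mass-shooting databases (SHR mass-killing subset, ASR,
Mother Jones, Everytown, Gun Violence Archive) operationalize "mass
shooting" differently, so their 2013–2020 incident lists overlap only
partially. `masslink` treats the comparison as a multi-source surveillance
reconciliation problem with four stages: harmonize each export into a common
record schema; encode each database's inclusion definition declaratively;
resolve cross-source duplicates (including *imperfect* duplicates that
disagree on a field or two) into incident clusters by deterministic record
linkage; and count exclusive set overlaps over the resulting incidents ×
sources membership matrix. Because the underlying databases are live and
cannot be re-downloaded reproducibly, correctness is established against a
synthetic five-database generator with exact ground truth, plus the
published per-source tallies whose internal arithmetic is fixed.

## Harmonization

Each source ships a dialect config (bundled YAML): column map, date format,
encoding, and whether the killed count includes the perpetrator. Dates are
parsed strictly against the dialect's format — no imputation; unparseable
rows go to a structured error report rather than being dropped silently.
State strings normalize to USPS codes via a fixed internal table; unmatched
values are kept verbatim and flagged. When a source counts the perpetrator
among the dead (the bundled Everytown dialect does), one is subtracted when
the shooter is recorded as killed; if the shooter's fate is unknown the
count is set unknown and flagged rather than guessed.

SHR is victim-level: one row per decedent. Rows are grouped into incidents
by (agency, incident number, date) — the standard SHR convention, exposed as
dialect configuration — and an incident's fatality count is its victim-row
count. The mass-killing subset retains incidents with exactly one shooter
and ≥4 fatalities from firearm weapon codes; the firearm code set is
configurable (default: handgun, rifle, shotgun, "firearm, type not stated",
"other gun"), records with unrecognized weapon codes route to a review list,
and every dropped record carries a reason code. SHR carries no injury
counts, so injured is unknown for SHR records and excluded from injury sums
(the summary tables report unknown-count tallies separately).

## Inclusion definitions

A `Definition` has a count basis (fatalities vs. casualties), threshold,
shooter-count bounds, an identified-shooter requirement, motive exclusions
and an optional location restriction. The five bundled presets encode the
published criteria: SHR {fatalities ≥4, exactly 1 shooter}; ASR {no
threshold; excludes gang/drug/family-IPV motives}; MJ {fatalities ≥3, 1
identified shooter; excludes robbery/gang/family-IPV}; Everytown
{fatalities ≥4, any motive}; GVA {casualties ≥4, 1–2 shooters}.

Unknown-field policy: count and shooter rules **fail closed** (an unknown
fatality count cannot clear a threshold), motive/location exclusions **fail
open** (only a documented excluded motive disqualifies), matching how
motive-restricted databases exclude known gang/drug/domestic incidents
without requiring motives to be established. Both behaviors are per-rule
configurable. MJ's documented two-shooter exceptions are supported by an
explicit allow-list on the definition, empty by default. MJ's ≥3 threshold
is applied uniformly across the window. The ASR notion of "randomness" is
modeled purely as motive-set exclusion; no further operationalization is
attempted.

## Linkage

Blocking admits a candidate pair iff the records come from different
sources, their states agree (unknown state is compatible with anything) and
their dates differ by at most the window (default ±1 day, reflecting
media-vs-report dating disagreement). Scoring computes per-field
similarities in [0,1] — exact state match; city and shooter-name similarity
as normalized edit distance (via edlib); count similarity
1 − |Δ|/max(a,b,1); date similarity 1 on the same day, decaying by
Δ/(2·(window+1)) inside the window — and combines them as a weighted mean
over the components present on both records (weights: date .25, state .20,
city .20, name .15, killed .10, injured .10, renormalized over present
components). The within-window date penalty is deliberately mild (at most
half the date weight): the window itself asserts that one-day jitter is
ordinary, so a lone date disagreement between otherwise identical records
should auto-link, while disagreement on several fields still lands in the
review band.

Pairs with total ≥ 0.90 are MATCH, ≥ 0.70 REVIEW, else NONMATCH; thresholds
are closed at the lower bound and fully configurable. REVIEW pairs export to
a CSV queue for human adjudication and resolutions import back; unresolved
REVIEW pairs default to NONMATCH with the affected clusters flagged.
Clusters are connected components over MATCH edges (networkx); singletons
stand alone; a cluster with two records from the same source is flagged, not
split, since real databases occasionally double-list. The canonical merged
record takes per-field **maximum** casualty counts ("at least" semantics
when sources disagree) and majority date/state/city with ties broken by
source priority SHR > ASR > Everytown > MJ > GVA. All orderings are stable
(date, state, source priority, source id), so fixed inputs give
byte-identical outputs.

With the default one-day window and threshold 0.90, blocking is exact, not
approximate: a pair differing by ≥2 days loses at least 0.125 of total
score, and a state mismatch at least 0.20, so no excluded pair could have
scored ≥0.90 — clustering equals all-pairs brute force (asserted on
instances up to 500 records).

## Overlap analytics

`build_membership` produces the boolean clusters × sources matrix; every row
has at least one true cell and column sums are per-source incident counts.
`exclusive_intersections` counts clusters per exact membership pattern
(UpSet convention — intersections are exclusive, so counts partition the
union). Restricting the source set (e.g. dropping GVA) drops rows with no
remaining member before counting. The threshold re-analysis filters
*clusters* on the canonical (max-merged) killed count — per-source summary
rows keep each source's own reported counts — and commutes with overlap
counting (filter-then-count equals count-then-row-filter, property-tested).
Shares are reported as computed ratios to 3 significant figures; note that
25 of 3155 incidents is 0.79%, not 0.008% as sometimes printed — the package
always outputs the computed ratio.

## Synthetic generator

The generator defines the test conditions. A universe of n incidents (2000
in the standard runs) draws: dates uniform in the 2013–2020 window with a
7-day interior margin (so one-day reporting jitter cannot cross the window
boundary); city/state from a bundled list of ~180 real U.S. cities (so typo
similarity behaves realistically); fatalities ~ NB(mean 2.0, dispersion 1.0)
and injuries ~ NB(mean 3.0, dispersion 1.0), with an all-zero (killed,
injured) pair redrawn jointly — every incident has ≥1 victim, but 0-killed
and 0-injured incidents both occur, which the GVA-vs-fatality-basis
contrasts require; two shooters with probability 0.05; perpetrator death
0.2; motives categorical (gang .25, family/IPV .25, drug .10, robbery .05,
terror .02, other .33). The negative binomial gives the overdispersed,
mostly-small-rarely-large severity skew of real incident data.

Each source then observes the universe: an incident ineligible under the
source's definition is never emitted; eligible incidents are detected with
probability 0.95; emitted fields are perturbed independently at 5% each
(date ±1 day, one-character city typo, one casualty count off by one, shooter
name dropped). Eligibility is fixed pre-perturbation, so a listed count can
disagree with the threshold — as happens in real databases. Exports are
written in each source's own dialect (SHR victim-level, Everytown
shooter-inclusive counts, MJ combined "City, State", GVA without shooter
names), so the readers are exercised end to end, and the ground truth
records every emission for exact truth-side clusters, membership and
overlap.

Under these defaults GVA emits the most incidents and MJ the fewest,
mirroring the real ordering (casualty basis ≥ fatality basis; MJ's
exclusions are strictest). What the generator does **not** emulate: shared
upstream news sourcing (real source errors are correlated, not
independent), county-level or multi-jurisdiction geography, within-incident
victim demographics, secular trends in incidence, and databases revising
entries over time. Passing tests therefore demonstrate correctness of the
mechanics and robustness to independent field noise, not performance on any
real snapshot.

## Problem sizes and numerical choices

Standard verification runs use a 2000-incident universe (clean run compared
exactly against the truth oracle; ten perturbed universes for
precision/recall, observed ≥0.98 for both), 500-record instances for
blocking-vs-brute-force equivalence, and ≥1000 randomized cases for the
monotonicity/conservation/partition property suite. Similarities are exact
rational arithmetic in float; classification bounds are closed at the lower
threshold; all tie-breaks are documented above. Degenerate inputs: empty
files warn and return empty; records without dates are never linkage
candidates; thresholds of 0 retain everything including unknown counts.

## Known limitations

Linkage is rule-based with fixed weights (no probabilistic Fellegi–Sunter
training), matching the adjudication-centred workflow it mirrors; precision
on real data will depend on how often distinct incidents share state, date
and city. The SHR subset filters on weapon codes, shooter count and
fatalities only — if a circumstance-field restriction is also desired it
must be added to the dialect. Counts of "incidents" are cluster counts and
inherit any linkage errors; the review queue exists precisely so borderline
pairs get human judgment.
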