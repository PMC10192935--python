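"""Cross-source incident linkage.

The same shooting typically appears in several databases with slightly
different values: dates shifted a day between media and report dating, city
spellings diverging, casualty counts off by one while tallies settle.  This
module resolves such *imperfect duplicates* into clusters, each cluster one
real-world incident:

1. :func:`block_pairs` — candidate pairs restricted to different sources,
   same state (when both known) and dates within a small window, so the
   comparison space stays linear in practice;
2. :func:`score_pair` — field-wise similarities combined into a weighted
   total in [0, 1];
3. :func:`classify_pair` — thresholds split pairs into MATCH / REVIEW /
   NONMATCH, with the review queue exported for human adjudication;
4. :func:`cluster_matches` — transitive closure over MATCH edges.

Defaults (weights, thresholds, the one-day date window) are configuration,
not doctrine; they are chosen so exact-field matches auto-link and
single-field disagreements route to review.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from datetime import date as Date

import edlib
import networkx as nx

from .records import SOURCE_ORDER, Source, SourceRecord


@dataclass(frozen=True)
class LinkageConfig:
    date_window_days: int = 1
    weights: dict = None  # type: ignore[assignment]
    t_match: float = 0.90
    t_review: float = 0.70

    def __post_init__(self) -> None:
        if self.weights is None:
            object.__setattr__(self, "weights", dict(DEFAULT_WEIGHTS))
        if not 0.0 <= self.t_review <= self.t_match <= 1.0:
            raise ValueError("need 0 <= t_review <= t_match <= 1")


DEFAULT_WEIGHTS = {
    "date_sim": 0.25,
    "state_sim": 0.20,
    "city_sim": 0.20,
    "name_sim": 0.15,
    "killed_sim": 0.10,
    "injured_sim": 0.10,
}


@dataclass(frozen=True)
class PairScore:
    record_a: SourceRecord
    record_b: SourceRecord
    components: dict  # component name -> similarity in [0,1]; absent if unknown
    total: float

    @property
    def pair_id(self) -> str:
        a, b = sorted([self.record_a.key, self.record_b.key])
        return f"{a[0]}:{a[1]}|{b[0]}:{b[1]}"


class MatchLabel(enum.Enum):
    MATCH = "MATCH"
    REVIEW = "REVIEW"
    NONMATCH = "NONMATCH"


@dataclass(frozen=True)
class MatchDecision:
    pair: PairScore
    label: MatchLabel
    rationale: str


@dataclass
class IncidentCluster:
    cluster_id: str
    members: list[SourceRecord]
    canonical: SourceRecord
    needs_review: bool = False

    @property
    def sources(self) -> frozenset[Source]:
        return frozenset(m.source for m in self.members)


# --- blocking ---------------------------------------------------------------

def block_pairs(
    records: list[SourceRecord], config: LinkageConfig = LinkageConfig()
) -> list[tuple[SourceRecord, SourceRecord]]:
    """Candidate pairs: different sources, compatible state, close dates.

    Complete with respect to those conditions: no pair meeting them is
    omitted.  Records lacking a date are never candidates; records lacking a
    state are compared against every state (state unknown is compatible with
    anything).
    """
    dated = sorted(
        (r for r in records if r.date is not None), key=SourceRecord.sort_key
    )
    pairs: list[tuple[SourceRecord, SourceRecord]] = []
    window = config.date_window_days
    for i, a in enumerate(dated):
        for b in dated[i + 1 :]:
            delta = (b.date - a.date).days
            if delta > window:
                break  # sorted by date; nothing further can qualify
            if a.source is b.source:
                continue
            if a.state is not None and b.state is not None and a.state != b.state:
                continue
            pairs.append((a, b))
    return pairs


# --- scoring ----------------------------------------------------------------

def _norm_text(s: str) -> str:
    return " ".join(s.lower().split())


def text_similarity(a: str, b: str) -> float:
    """Normalized edit-distance similarity: 1 - dist / max(len)."""
    a, b = _norm_text(a), _norm_text(b)
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _count_similarity(a: int, b: int) -> float:
    return max(0.0, 1.0 - abs(a - b) / max(a, b, 1))


def score_pair(
    a: SourceRecord,
    b: SourceRecord,
    config: LinkageConfig = LinkageConfig(),
) -> PairScore:
    """Field-wise similarity components and their weighted mean.

    A component is absent when either side's field is unknown; the weighted
    mean renormalizes over the components actually present.  date_sim is 1
    exactly on same-day pairs and decays linearly to 0 just outside the
    blocking window.
    """
    comp: dict[str, float] = {}
    if a.date is not None and b.date is not None:
        # A disagreement inside the blocking window is ordinary reporting
        # jitter (media vs. report dating), so it costs at most half the date
        # component; only same-day pairs score 1.
        delta = abs((a.date - b.date).days)
        comp["date_sim"] = max(
            0.0, 1.0 - delta / (2.0 * (config.date_window_days + 1))
        )
    if a.state is not None and b.state is not None:
        comp["state_sim"] = 1.0 if a.state == b.state else 0.0
    if a.city is not None and b.city is not None:
        comp["city_sim"] = text_similarity(a.city, b.city)
    if a.shooter_names and b.shooter_names:
        comp["name_sim"] = max(
            text_similarity(x, y) for x in a.shooter_names for y in b.shooter_names
        )
    if a.killed_excl_perp is not None and b.killed_excl_perp is not None:
        comp["killed_sim"] = _count_similarity(a.killed_excl_perp, b.killed_excl_perp)
    if a.injured_excl_perp is not None and b.injured_excl_perp is not None:
        comp["injured_sim"] = _count_similarity(
            a.injured_excl_perp, b.injured_excl_perp
        )

    wsum = sum(config.weights[k] for k in comp)
    total = (
        sum(config.weights[k] * v for k, v in comp.items()) / wsum if wsum else 0.0
    )
    return PairScore(a, b, comp, total)


def classify_pair(
    score: PairScore, t_match: float, t_review: float
) -> MatchDecision:
    """MATCH if total >= t_match; REVIEW if t_review <= total < t_match."""
    if not 0.0 <= t_review <= t_match <= 1.0:
        raise ValueError("need 0 <= t_review <= t_match <= 1")
    if score.total >= t_match:
        label = MatchLabel.MATCH
    elif score.total >= t_review:
        label = MatchLabel.REVIEW
    else:
        label = MatchLabel.NONMATCH
    return MatchDecision(
        score, label, f"total={score.total:.4f} vs (match>={t_match}, review>={t_review})"
    )


def decide_pairs(
    records: list[SourceRecord], config: LinkageConfig = LinkageConfig()
) -> list[MatchDecision]:
    """Block, score and classify in one pass."""
    return [
        classify_pair(score_pair(a, b, config), config.t_match, config.t_review)
        for a, b in block_pairs(records, config)
    ]


# --- clustering -------------------------------------------------------------

def _majority(values: list, priorities: list[int]):
    """Most frequent value; ties broken by best (lowest) source priority."""
    counts: dict = {}
    best_priority: dict = {}
    for v, p in zip(values, priorities):
        counts[v] = counts.get(v, 0) + 1
        best_priority[v] = min(best_priority.get(v, p), p)
    return max(counts, key=lambda v: (counts[v], -best_priority[v]))


def merge_canonical(members: list[SourceRecord]) -> SourceRecord:
    """Merge cluster members into one canonical record.

    Casualty counts take the per-field maximum across members ("at least"
    semantics, since sources routinely disagree); date, state and city take
    the majority value with ties broken by source priority
    SHR > ASR > EVERYTOWN > MJ > GVA; shooter names are unioned.
    """
    members = sorted(members, key=SourceRecord.sort_key)
    prio = [SOURCE_ORDER.index(m.source) for m in members]

    def maj(values):
        known = [(v, p) for v, p in zip(values, prio) if v is not None]
        if not known:
            return None
        return _majority([v for v, _ in known], [p for _, p in known])

    def field_max(values):
        known = [v for v in values if v is not None]
        return max(known) if known else None

    names: list[str] = []
    for m in members:
        for n in m.shooter_names:
            if n not in names:
                names.append(n)
    base = members[0]
    return replace(
        base,
        date=maj([m.date for m in members]),
        state=maj([m.state for m in members]),
        city=maj([m.city for m in members]),
        shooter_names=names,
        n_shooters=field_max([m.n_shooters for m in members]),
        killed_excl_perp=field_max([m.killed_excl_perp for m in members]),
        injured_excl_perp=field_max([m.injured_excl_perp for m in members]),
        perp_died=maj([m.perp_died for m in members]),
        motive_tags=frozenset().union(*(m.motive_tags for m in members)),
        raw={},
        flags=set().union(*(m.flags for m in members)),
    )


def cluster_matches(
    records: list[SourceRecord],
    decisions: list[MatchDecision],
    review_resolutions: dict[str, MatchLabel] | None = None,
) -> list[IncidentCluster]:
    """Connected components over MATCH edges; singletons stand alone.

    ``review_resolutions`` maps pair ids of REVIEW decisions to
    MATCH/NONMATCH; unresolved REVIEW pairs default to NONMATCH and flag the
    affected clusters for review.  Clusters holding two records from the same
    source are flagged, not split (real databases occasionally double-list).
    """
    review_resolutions = review_resolutions or {}
    for pid, label in review_resolutions.items():
        if label not in (MatchLabel.MATCH, MatchLabel.NONMATCH):
            raise ValueError(f"resolution for {pid} must be MATCH or NONMATCH")

    g = nx.Graph()
    for r in records:
        g.add_node(r.key, record=r)
    unresolved_review_nodes: set = set()
    for d in decisions:
        label = d.label
        if label is MatchLabel.REVIEW:
            label = review_resolutions.get(d.pair.pair_id, None)
            if label is None:
                unresolved_review_nodes.add(d.pair.record_a.key)
                unresolved_review_nodes.add(d.pair.record_b.key)
                continue
        if label is MatchLabel.MATCH:
            g.add_edge(d.pair.record_a.key, d.pair.record_b.key)

    clusters: list[IncidentCluster] = []
    for component in nx.connected_components(g):
        members = sorted(
            (g.nodes[k]["record"] for k in component), key=SourceRecord.sort_key
        )
        lead = members[0]
        cluster_id = (
            f"{lead.date.isoformat() if lead.date else 'nodate'}"
            f"-{lead.state or 'XX'}-{lead.source.value}-{lead.source_id}"
        )
        sources = [m.source for m in members]
        needs_review = len(sources) != len(set(sources)) or any(
            m.key in unresolved_review_nodes for m in members
        )
        clusters.append(
            IncidentCluster(
                cluster_id=cluster_id,
                members=members,
                canonical=merge_canonical(members),
                needs_review=needs_review,
            )
        )
    clusters.sort(key=lambda c: c.members[0].sort_key())
    return clusters


def link_records(
    records: list[SourceRecord],
    config: LinkageConfig = LinkageConfig(),
    review_resolutions: dict[str, MatchLabel] | None = None,
) -> tuple[list[IncidentCluster], list[MatchDecision]]:
    """Full linkage pass: block, score, classify, cluster."""
    decisions = decide_pairs(records, config)
    return cluster_matches(records, decisions, review_resolutions), decisions


# --- review queue ------------------------------------------------------------

REVIEW_COLUMNS = [
    "pair_id",
    "source_a",
    "id_a",
    "source_b",
    "id_b",
    "date_sim",
    "state_sim",
    "city_sim",
    "name_sim",
    "killed_sim",
    "injured_sim",
    "total",
    "resolution",
]


def export_review_queue(decisions: list[MatchDecision], path) -> int:
    """Write REVIEW pairs to CSV for human adjudication; returns row count."""
    rows = sorted(
        (d for d in decisions if d.label is MatchLabel.REVIEW),
        key=lambda d: d.pair.pair_id,
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REVIEW_COLUMNS)
        for d in rows:
            p = d.pair
            a, b = sorted([p.record_a.key, p.record_b.key])
            w.writerow(
                [p.pair_id, a[0], a[1], b[0], b[1]]
                + [
                    f"{p.components[c]:.6f}" if c in p.components else ""
                    for c in REVIEW_COLUMNS[5:11]
                ]
                + [f"{p.total:.6f}", ""]
            )
    return len(rows)


def import_review(path) -> dict[str, MatchLabel]:
    """Read adjudicated review CSV back into a resolutions mapping.

    Rows with an empty resolution are preserved as unresolved (omitted from
    the mapping); anything other than MATCH/NONMATCH/blank is an error naming
    the row.
    """
    resolutions: dict[str, MatchLabel] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=1):
            value = (row.get("resolution") or "").strip().upper()
            if not value:
                continue
            if value not in ("MATCH", "NONMATCH"):
                raise ValueError(
                    f"row {i} (pair {row.get('pair_id')}): bad resolution "
                    f"{value!r}, expected MATCH or NONMATCH"
                )
            resolutions[row["pair_id"]] = MatchLabel[value]
    return resolutions


def write_clusters_csv(clusters: list[IncidentCluster], path) -> None:
    """One row per (cluster, member); deterministic order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["cluster_id", "source", "source_id", "date", "state", "city",
             "killed_excl_perp", "injured_excl_perp", "needs_review"]
        )
        for c in clusters:
            for m in c.members:
                w.writerow(
                    [
                        c.cluster_id,
                        m.source.value,
                        m.source_id,
                        m.date.isoformat() if m.date else "",
                        m.state or "",
                        m.city or "",
                        "" if m.killed_excl_perp is None else m.killed_excl_perp,
                        "" if m.injured_excl_perp is None else m.injured_excl_perp,
                        str(c.needs_review).lower(),
                    ]
                )
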