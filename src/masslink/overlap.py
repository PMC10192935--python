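"""Set-overlap analytics over linked incident clusters.

Once cross-source records are resolved into clusters, every cluster has a
membership pattern — the subset of databases that list it.  The boolean
incidents x sources :class:`MembershipMatrix` underlies every overlap count:
per-database totals are its column sums, the union of all databases is its
row count, and the UpSet-style analysis counts clusters per *exclusive*
membership pattern (a cluster counts toward exactly the subset equal to its
full pattern, so the counts partition the union).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import pandas as pd

from .linkage import IncidentCluster
from .records import SOURCE_ORDER, Source, SourceRecord


@dataclass
class MembershipMatrix:
    """Boolean clusters x sources table."""

    data: pd.DataFrame  # index: cluster_id, columns: source names, dtype bool

    def __post_init__(self) -> None:
        if len(self.data) and not self.data.any(axis=1).all():
            raise ValueError("membership matrix has an all-false row")

    @property
    def sources(self) -> list[str]:
        return list(self.data.columns)

    @property
    def union_total(self) -> int:
        return len(self.data)

    def column_counts(self) -> dict[str, int]:
        return {s: int(self.data[s].sum()) for s in self.data.columns}

    def restrict(self, sources: list[Source | str]) -> "MembershipMatrix":
        """Drop all other source columns, then rows with no member left."""
        cols = [s.value if isinstance(s, Source) else s for s in sources]
        sub = self.data[cols]
        return MembershipMatrix(sub[sub.any(axis=1)])


@dataclass
class OverlapSummary:
    """Exclusive intersection counts keyed by source-subset tuples."""

    exclusive_counts: dict[tuple[str, ...], int]
    union_total: int
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if sum(self.exclusive_counts.values()) != self.union_total:
            raise ValueError("exclusive counts must sum to the union total")

    @property
    def full_intersection(self) -> int:
        return self.exclusive_counts.get(tuple(self.sources), 0)

    def count(self, subset) -> int:
        names = [s.value if isinstance(s, Source) else s for s in subset]
        key = tuple(sorted(names, key=self.sources.index))
        return self.exclusive_counts.get(key, 0)


def build_membership(
    clusters: list[IncidentCluster],
    sources: list[Source] | None = None,
) -> MembershipMatrix:
    """Membership matrix from clusters; restricting ``sources`` drops
    clusters with no member among them."""
    sources = list(sources) if sources is not None else list(SOURCE_ORDER)
    cols = [s.value for s in sources]
    rows, index = [], []
    seen: set[str] = set()
    for c in clusters:
        if c.cluster_id in seen:
            raise ValueError(f"duplicate cluster id {c.cluster_id}")
        seen.add(c.cluster_id)
        present = {m.source for m in c.members}
        row = [s in present for s in sources]
        if any(row):
            rows.append(row)
            index.append(c.cluster_id)
    return MembershipMatrix(
        pd.DataFrame(rows, index=index, columns=cols, dtype=bool)
    )


def exclusive_intersections(matrix: MembershipMatrix) -> OverlapSummary:
    """Count clusters per exact membership pattern (UpSet convention)."""
    counts: dict[tuple[str, ...], int] = {}
    cols = matrix.sources
    if len(matrix.data):
        arr = matrix.data.to_numpy()
        for row in arr:
            key = tuple(c for c, present in zip(cols, row) if present)
            counts[key] = counts.get(key, 0) + 1
    return OverlapSummary(counts, matrix.union_total, tuple(cols))


def summarize_sources(
    records_by_source: dict[Source, list[SourceRecord]]
) -> pd.DataFrame:
    """Per-source table: incidents, total fatalities/injuries, unknown counts.

    Unknown casualty fields are excluded from the sums and tallied in the
    ``*_unknown`` columns.
    """
    rows = []
    for source in SOURCE_ORDER:
        if source not in records_by_source:
            continue
        records = records_by_source[source]
        killed = [r.killed_excl_perp for r in records]
        injured = [r.injured_excl_perp for r in records]
        rows.append(
            {
                "source": source.value,
                "incidents": len(records),
                "total_fatalities": sum(k for k in killed if k is not None),
                "total_injured": sum(i for i in injured if i is not None),
                "fatalities_unknown": sum(k is None for k in killed),
                "injured_unknown": sum(i is None for i in injured),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source",
            "incidents",
            "total_fatalities",
            "total_injured",
            "fatalities_unknown",
            "injured_unknown",
        ],
    )


def export_upset_data(summary: OverlapSummary, path=None) -> pd.DataFrame:
    """UpSet-format table: one row per nonempty subset.

    Indicator column per source plus ``count``; sorted by count descending,
    ties by subset size then lexicographic — deterministic under re-run.
    Consumable by standard UpSet plotting tools.
    """
    rows = []
    for subset, count in summary.exclusive_counts.items():
        row = {s: (s in subset) for s in summary.sources}
        row["count"] = count
        rows.append(row)
    df = pd.DataFrame(rows, columns=[*summary.sources, "count"])
    if len(df):
        df["_size"] = df[list(summary.sources)].sum(axis=1)
        df["_lex"] = [
            "".join("1" if r else "0" for r in row)
            for row in df[list(summary.sources)].to_numpy()
        ]
        df = df.sort_values(
            ["count", "_size", "_lex"], ascending=[False, True, True]
        ).drop(columns=["_size", "_lex"]).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def import_upset_data(path) -> OverlapSummary:
    """Inverse of :func:`export_upset_data`; round-trip stable."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        sources = tuple(c for c in reader.fieldnames if c != "count")
        counts: dict[tuple[str, ...], int] = {}
        for row in reader:
            subset = tuple(s for s in sources if row[s] == "True")
            counts[subset] = counts.get(subset, 0) + int(row["count"])
    return OverlapSummary(counts, sum(counts.values()), sources)


def plot_upset(summary: OverlapSummary, path) -> None:
    """Minimal UpSet rendering: intersection bars over a membership dot grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = export_upset_data(summary)
    n_sets = len(summary.sources)
    fig, (ax_bar, ax_dots) = plt.subplots(
        2, 1, figsize=(max(6, 0.45 * len(df)), 5),
        sharex=True, height_ratios=[2, 1],
    )
    x = range(len(df))
    ax_bar.bar(x, df["count"], color="0.2")
    for i, c in enumerate(df["count"]):
        ax_bar.text(i, c, str(c), ha="center", va="bottom", fontsize=7)
    ax_bar.set_ylabel("incidents (exclusive)")
    for i in x:
        for j, s in enumerate(summary.sources):
            on = bool(df.iloc[i][s])
            ax_dots.plot(i, j, "o", color="0.2" if on else "0.85", ms=6)
    ax_dots.set_yticks(range(n_sets), summary.sources)
    ax_dots.set_ylim(-0.5, n_sets - 0.5)
    ax_dots.invert_yaxis()
    ax_dots.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
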