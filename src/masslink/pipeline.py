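"""End-to-end orchestration: load, subset, harmonize, link, overlap, report.

The pipeline is deterministic: fixed inputs and configuration produce
byte-identical outputs.  Three overlap analyses are produced as named report
sections — all five sources, the four sources excluding GVA (whose
casualty-basis threshold dominates the union), and the subset of incidents
meeting the conservative >=4-fatality definition — plus arbitrary source
subsets via configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from datetime import date as Date
from pathlib import Path

from . import readers
from .definitions import apply_fatality_threshold
from .linkage import (
    IncidentCluster,
    LinkageConfig,
    MatchLabel,
    cluster_matches,
    decide_pairs,
    export_review_queue,
    write_clusters_csv,
)
from .overlap import (
    MembershipMatrix,
    OverlapSummary,
    build_membership,
    exclusive_intersections,
    export_upset_data,
    summarize_sources,
)
from .records import SOURCE_ORDER, Source, SourceRecord

log = logging.getLogger("masslink")


@dataclass
class PipelineConfig:
    source_paths: dict[Source, str | Path]
    dialects: dict[Source, readers.SourceDialect] = dc_field(default_factory=dict)
    window_start: Date = Date(2013, 1, 1)
    window_end: Date = Date(2020, 12, 31)
    linkage: LinkageConfig = dc_field(default_factory=LinkageConfig)
    fatality_threshold: int = 4
    sources: tuple[Source, ...] = SOURCE_ORDER
    out_dir: str | Path | None = None
    review_resolutions: dict[str, MatchLabel] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ValueError("window_start must be <= window_end")
        for source, path in self.source_paths.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{source.value}: {path}")

    def dialect_for(self, source: Source) -> readers.SourceDialect:
        return self.dialects.get(source) or readers.builtin_dialect(source)


@dataclass
class ReportBundle:
    records_by_source: dict[Source, list[SourceRecord]]
    parse_errors: list[readers.ParseError]
    clusters: list[IncidentCluster]
    membership: MembershipMatrix
    overlap_all: OverlapSummary
    overlap_excl_gva: OverlapSummary
    overlap_min4: OverlapSummary
    summary_table: "object"  # pandas DataFrame
    n_review_pairs: int

    @property
    def union_total(self) -> int:
        return self.overlap_all.union_total


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run every stage, logging record counts throughout.

    Any stage failure aborts with a stage-named error message.
    """
    stage = "load"
    try:
        records_by_source: dict[Source, list[SourceRecord]] = {}
        errors: list[readers.ParseError] = []
        for source in cfg.sources:
            result = readers.load_source(
                cfg.source_paths[source], cfg.dialect_for(source)
            )
            errors.extend(result.errors)
            records = result.records
            log.info(
                "load %s: %d records, %d parse errors",
                source.value, len(records), len(result.errors),
            )
            if source is Source.SHR:
                stage = "subset_shr"
                sub = readers.subset_shr(records)
                log.info(
                    "subset_shr: %d retained, %d dropped, %d to review",
                    len(sub.retained), len(sub.dropped), len(sub.review),
                )
                records = sub.retained
                stage = "load"
            records_by_source[source] = records

        stage = "filter_window"
        for source in records_by_source:
            before = len(records_by_source[source])
            records_by_source[source] = readers.filter_window(
                records_by_source[source], cfg.window_start, cfg.window_end
            )
            log.info(
                "window %s: %d -> %d", source.value, before,
                len(records_by_source[source]),
            )

        stage = "harmonize"
        harmonized = readers.harmonize(
            [r for rs in records_by_source.values() for r in rs]
        )
        records_by_source = {
            s: [r for r in harmonized if r.source is s] for s in cfg.sources
        }
        log.info("harmonize: %d records total", len(harmonized))

        stage = "link"
        decisions = decide_pairs(harmonized, cfg.linkage)
        clusters = cluster_matches(harmonized, decisions, cfg.review_resolutions)
        n_review = sum(d.label is MatchLabel.REVIEW for d in decisions)
        log.info(
            "link: %d candidate pairs, %d review, %d clusters",
            len(decisions), n_review, len(clusters),
        )

        stage = "overlap"
        membership = build_membership(clusters, list(cfg.sources))
        overlap_all = exclusive_intersections(membership)
        non_gva = [s for s in cfg.sources if s is not Source.GVA]
        overlap_excl_gva = exclusive_intersections(membership.restrict(non_gva))
        retained, _ = apply_fatality_threshold(clusters, cfg.fatality_threshold)
        overlap_min4 = exclusive_intersections(
            build_membership(retained, list(cfg.sources))
        )
        log.info(
            "overlap: union=%d, full intersection=%d; minus-GVA union=%d; "
            ">=%d-fatality union=%d",
            overlap_all.union_total, overlap_all.full_intersection,
            overlap_excl_gva.union_total, cfg.fatality_threshold,
            overlap_min4.union_total,
        )

        stage = "report"
        summary = summarize_sources(records_by_source)
        bundle = ReportBundle(
            records_by_source=records_by_source,
            parse_errors=errors,
            clusters=clusters,
            membership=membership,
            overlap_all=overlap_all,
            overlap_excl_gva=overlap_excl_gva,
            overlap_min4=overlap_min4,
            summary_table=summary,
            n_review_pairs=n_review,
        )
        if cfg.out_dir is not None:
            _write_bundle(bundle, decisions, cfg)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _write_bundle(bundle: ReportBundle, decisions, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.summary_table.to_csv(out / "source_summary.csv", index=False)
    write_clusters_csv(bundle.clusters, out / "clusters.csv")
    export_review_queue(decisions, out / "review_queue.csv")
    readers.write_errors_csv(bundle.parse_errors, out / "parse_errors.csv")
    export_upset_data(bundle.overlap_all, out / "overlap_all.csv")
    export_upset_data(bundle.overlap_excl_gva, out / "overlap_excl_gva.csv")
    export_upset_data(
        bundle.overlap_min4, out / f"overlap_min{cfg.fatality_threshold}.csv"
    )
    report = {
        "union_total": bundle.overlap_all.union_total,
        "full_intersection": bundle.overlap_all.full_intersection,
        "union_excl_gva": bundle.overlap_excl_gva.union_total,
        "full_intersection_excl_gva": bundle.overlap_excl_gva.full_intersection,
        "fatality_threshold": cfg.fatality_threshold,
        "union_at_threshold": bundle.overlap_min4.union_total,
        "full_intersection_at_threshold": bundle.overlap_min4.full_intersection,
        "per_source_incidents": bundle.membership.column_counts(),
        "full_intersection_share": (
            round(
                bundle.overlap_all.full_intersection
                / bundle.overlap_all.union_total,
                6,
            )
            if bundle.overlap_all.union_total
            else None
        ),
        "review_pairs": bundle.n_review_pairs,
        "parse_errors": len(bundle.parse_errors),
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
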