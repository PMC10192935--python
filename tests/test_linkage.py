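"""Blocking, pair scoring, classification, clustering, review round-trip."""

from __future__ import annotations

import itertools
from datetime import date as Date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from masslink import (
    LinkageConfig,
    MatchLabel,
    Source,
    block_pairs,
    classify_pair,
    cluster_matches,
    score_pair,
)
from masslink.linkage import (
    MatchDecision,
    PairScore,
    decide_pairs,
    export_review_queue,
    import_review,
    merge_canonical,
    write_clusters_csv,
)

from conftest import make_record


def random_records(n, rng, n_states=4, span_days=30):
    states = ["TX", "OH", "CA", "NY", "FL", "WA"][:n_states]
    cities = ["Houston", "Dayton", "Fresno", "Buffalo", "Miami", "Tacoma"]
    sources = list(Source)
    out = []
    for i in range(n):
        out.append(
            make_record(
                source=sources[int(rng.integers(len(sources)))],
                source_id=f"r{i}",
                date=Date(2015, 1, 1) + timedelta(days=int(rng.integers(span_days))),
                state=states[int(rng.integers(len(states)))],
                city=cities[int(rng.integers(len(cities)))],
                shooter_names=(f"Shooter {rng.integers(20)}",),
                killed=int(rng.integers(0, 8)),
                injured=int(rng.integers(0, 8)),
            )
        )
    return out


class TestBlocking:
    def test_same_state_same_day_different_sources_is_candidate(self):
        a = make_record(source=Source.GVA)
        b = make_record(source=Source.MJ, source_id="r2")
        pairs = block_pairs([a, b])
        assert len(pairs) == 1
        assert {pairs[0][0].key, pairs[0][1].key} == {a.key, b.key}

    def test_different_states_never_candidates(self):
        a = make_record(source=Source.GVA, state="TX")
        b = make_record(source=Source.MJ, source_id="r2", state="OH")
        assert block_pairs([a, b]) == []

    def test_same_source_never_candidates(self):
        a = make_record(source=Source.GVA, source_id="r1")
        b = make_record(source=Source.GVA, source_id="r2")
        assert block_pairs([a, b]) == []

    def test_unknown_state_is_compatible_with_any(self):
        a = make_record(source=Source.GVA, state=None)
        b = make_record(source=Source.MJ, source_id="r2", state="OH")
        assert len(block_pairs([a, b])) == 1

    def test_matches_exhaustive_pair_oracle_on_300_records(self):
        rng = np.random.default_rng(13)
        records = random_records(300, rng)
        cfg = LinkageConfig()
        got = {
            frozenset((a.key, b.key)) for a, b in block_pairs(records, cfg)
        }
        want = {
            frozenset((a.key, b.key))
            for a, b in itertools.combinations(records, 2)
            if a.source is not b.source
            and a.state == b.state
            and abs((a.date - b.date).days) <= cfg.date_window_days
        }
        assert got == want


class TestScoring:
    def test_identical_records_score_one(self):
        a = make_record(source=Source.GVA)
        b = make_record(source=Source.MJ, source_id="r2")
        assert score_pair(a, b).total == pytest.approx(1.0)

    def test_killed_four_vs_five_gives_point_eight_similarity(self):
        a = make_record(source=Source.GVA, killed=4)
        b = make_record(source=Source.MJ, source_id="r2", killed=5)
        s = score_pair(a, b)
        assert s.components["killed_sim"] == pytest.approx(1 - 1 / 5)

    def test_date_sim_is_one_only_on_same_day(self):
        a = make_record(source=Source.GVA)
        same = make_record(source=Source.MJ, source_id="r2")
        shifted = make_record(
            source=Source.MJ, source_id="r3", date=a.date + timedelta(days=1)
        )
        assert score_pair(a, same).components["date_sim"] == 1.0
        assert score_pair(a, shifted).components["date_sim"] < 1.0

    def test_components_absent_when_either_field_unknown(self):
        a = make_record(source=Source.GVA, shooter_names=(), killed=None)
        b = make_record(source=Source.MJ, source_id="r2")
        comp = score_pair(a, b).components
        assert "name_sim" not in comp and "killed_sim" not in comp
        assert 0.0 <= score_pair(a, b).total <= 1.0

    def test_perturbed_twin_scores_above_match_threshold(self):
        a = make_record(source=Source.GVA, city="Springfield")
        twin = make_record(
            source=Source.MJ,
            source_id="r2",
            city="Springfeld",                      # 1-char typo
            date=a.date + timedelta(days=1),        # 1-day shift
        )
        cfg = LinkageConfig()
        assert score_pair(a, twin, cfg).total >= cfg.t_match


class TestClassification:
    def _score(self, total):
        a = make_record(source=Source.GVA)
        b = make_record(source=Source.MJ, source_id="r2")
        return PairScore(a, b, {}, total)

    @pytest.mark.parametrize(
        "total,label",
        [
            (1.0, MatchLabel.MATCH),
            (0.90, MatchLabel.MATCH),     # closed lower bound
            (0.899, MatchLabel.REVIEW),
            (0.70, MatchLabel.REVIEW),
            (0.699, MatchLabel.NONMATCH),
            (0.0, MatchLabel.NONMATCH),
        ],
    )
    def test_threshold_boundaries(self, total, label):
        assert classify_pair(self._score(total), 0.90, 0.70).label is label

    def test_sweep_matches_interval_membership_oracle(self):
        rng = np.random.default_rng(17)
        for total in rng.random(1000):
            label = classify_pair(self._score(total), 0.9, 0.7).label
            if total >= 0.9:
                assert label is MatchLabel.MATCH
            elif total >= 0.7:
                assert label is MatchLabel.REVIEW
            else:
                assert label is MatchLabel.NONMATCH

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(self._score(0.5), 0.7, 0.9)


class TestClustering:
    def test_no_match_edges_yield_singletons(self):
        rng = np.random.default_rng(19)
        records = random_records(20, rng)
        clusters = cluster_matches(records, [])
        assert len(clusters) == 20
        assert all(len(c.members) == 1 for c in clusters)

    def test_transitive_closure_merges_chains(self):
        a = make_record(source=Source.GVA, source_id="a")
        b = make_record(source=Source.MJ, source_id="b")
        c = make_record(source=Source.ASR, source_id="c")

        def match(x, y):
            return MatchDecision(PairScore(x, y, {}, 1.0), MatchLabel.MATCH, "")

        clusters = cluster_matches([a, b, c], [match(a, b), match(b, c)])
        assert len(clusters) == 1
        assert {m.source_id for m in clusters[0].members} == {"a", "b", "c"}

    def test_partition_property_on_randomized_inputs(self):
        rng = np.random.default_rng(23)
        records = random_records(120, rng)
        clusters, _ = _pipeline_clusters(records)
        keys = [m.key for c in clusters for m in c.members]
        assert len(keys) == len(records)
        assert len(set(keys)) == len(keys)

    def test_same_source_members_flag_cluster_for_review(self):
        a = make_record(source=Source.GVA, source_id="a")
        b = make_record(source=Source.GVA, source_id="b")
        d = MatchDecision(PairScore(a, b, {}, 1.0), MatchLabel.MATCH, "")
        (cluster,) = cluster_matches([a, b], [d])
        assert cluster.needs_review

    def test_unresolved_review_defaults_to_nonmatch_with_flag(self):
        a = make_record(source=Source.GVA, source_id="a")
        b = make_record(source=Source.MJ, source_id="b")
        d = MatchDecision(PairScore(a, b, {}, 0.8), MatchLabel.REVIEW, "")
        clusters = cluster_matches([a, b], [d])
        assert len(clusters) == 2
        assert all(c.needs_review for c in clusters)
        resolved = cluster_matches(
            [a, b], [d], {d.pair.pair_id: MatchLabel.MATCH}
        )
        assert len(resolved) == 1 and not resolved[0].needs_review

    def test_invalid_resolution_label_rejected(self):
        a = make_record(source=Source.GVA, source_id="a")
        b = make_record(source=Source.MJ, source_id="b")
        d = MatchDecision(PairScore(a, b, {}, 0.8), MatchLabel.REVIEW, "")
        with pytest.raises(ValueError):
            cluster_matches([a, b], [d], {d.pair.pair_id: MatchLabel.REVIEW})


def _pipeline_clusters(records, cfg=LinkageConfig()):
    decisions = decide_pairs(records, cfg)
    return cluster_matches(records, decisions), decisions


def _bruteforce_clusters(records, cfg=LinkageConfig()):
    """All cross-source pairs scored, no blocking; same thresholds."""
    decisions = [
        classify_pair(score_pair(a, b, cfg), cfg.t_match, cfg.t_review)
        for a, b in itertools.combinations(records, 2)
        if a.source is not b.source
    ]
    return cluster_matches(records, decisions)


@pytest.mark.parametrize("n,seed", [(100, 29), (300, 31), (500, 37)])
def test_blocking_pipeline_equals_bruteforce_all_pairs(n, seed):
    rng = np.random.default_rng(seed)
    records = random_records(n, rng, n_states=3, span_days=20)
    blocked, _ = _pipeline_clusters(records)
    brute = _bruteforce_clusters(records)
    as_sets = lambda cs: {frozenset(m.key for m in c.members) for c in cs}
    assert as_sets(blocked) == as_sets(brute)


class TestCanonicalMerge:
    def test_counts_take_per_field_maximum(self):
        a = make_record(source=Source.GVA, killed=4, injured=7)
        b = make_record(source=Source.MJ, source_id="r2", killed=5, injured=2)
        merged = merge_canonical([a, b])
        assert merged.killed_excl_perp == 5
        assert merged.injured_excl_perp == 7

    def test_majority_wins_ties_broken_by_source_priority(self):
        d1, d2 = Date(2015, 6, 1), Date(2015, 6, 2)
        shr = make_record(source=Source.SHR, source_id="s", date=d1)
        gva = make_record(source=Source.GVA, source_id="g", date=d2)
        mj = make_record(source=Source.MJ, source_id="m", date=d2)
        assert merge_canonical([shr, gva]).date == d1   # tie -> SHR outranks GVA
        assert merge_canonical([shr, gva, mj]).date == d2  # majority wins


class TestReviewQueue:
    def test_zero_review_pairs_writes_header_only(self, tmp_path):
        p = tmp_path / "review.csv"
        assert export_review_queue([], p) == 0
        assert p.read_text().strip() == (
            "pair_id,source_a,id_a,source_b,id_b,date_sim,state_sim,city_sim,"
            "name_sim,killed_sim,injured_sim,total,resolution"
        )
        assert import_review(p) == {}

    def test_export_import_export_is_a_fixed_point(self, tmp_path):
        rng = np.random.default_rng(41)
        records = random_records(80, rng)
        _, decisions = _pipeline_clusters(records)
        p1, p2 = tmp_path / "r1.csv", tmp_path / "r2.csv"
        n = export_review_queue(decisions, p1)
        import_review(p1)  # unresolved rows survive the round trip
        export_review_queue(decisions, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert n == sum(d.label is MatchLabel.REVIEW for d in decisions)

    def test_resolutions_round_trip(self, tmp_path):
        a = make_record(source=Source.GVA, source_id="a")
        b = make_record(source=Source.MJ, source_id="b")
        d = MatchDecision(PairScore(a, b, {"date_sim": 1.0}, 0.8), MatchLabel.REVIEW, "")
        p = tmp_path / "review.csv"
        export_review_queue([d], p)
        header, row = p.read_text().splitlines()
        assert row.endswith(",")  # unresolved
        p.write_text(f"{header}\n{row}MATCH\n")
        assert import_review(p) == {d.pair.pair_id: MatchLabel.MATCH}

    def test_malformed_resolution_names_the_row(self, tmp_path):
        a = make_record(source=Source.GVA, source_id="a")
        b = make_record(source=Source.MJ, source_id="b")
        d = MatchDecision(PairScore(a, b, {}, 0.8), MatchLabel.REVIEW, "")
        p = tmp_path / "review.csv"
        export_review_queue([d], p)
        header, row = p.read_text().splitlines()
        p.write_text(f"{header}\n{row}MAYBE\n")
        with pytest.raises(ValueError, match="row 1"):
            import_review(p)


def test_cluster_output_deterministic_bytes(tmp_path):
    rng = np.random.default_rng(43)
    records = random_records(150, rng)
    p1, p2 = tmp_path / "c1.csv", tmp_path / "c2.csv"
    write_clusters_csv(_pipeline_clusters(records)[0], p1)
    write_clusters_csv(_pipeline_clusters(list(records))[0], p2)
    assert p1.read_bytes() == p2.read_bytes()


@given(st.data())
@settings(max_examples=150, derandomize=True, deadline=None)
def test_cluster_partition_property_hypothesis(data):
    """Every record lands in exactly one cluster; sizes sum to the input."""
    n = data.draw(st.integers(0, 40))
    seed = data.draw(st.integers(0, 2**20))
    records = random_records(n, np.random.default_rng(seed))
    clusters, _ = _pipeline_clusters(records)
    keys = [m.key for c in clusters for m in c.members]
    assert sorted(set(keys)) == sorted(keys)
    assert len(keys) == n
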