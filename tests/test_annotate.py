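"""Per-read annotation, bucket semantics, summary statistics, TSV output."""

import io

import numpy as np
import pytest

from tagtrie import (
    MappingSummary,
    PutativeTag,
    QueryRead,
    SearchBudget,
    SiteSpec,
    annotate_all,
    annotate_read,
    build_tag_database,
    build_trie,
    make_reads,
    write_annotation,
)
from tagtrie.annotate import format_record, header_line

CATG = SiteSpec("CATG")


def small_db():
    streams = {
        "db1": [PutativeTag("CATGAA", "db1", "tx1", 0, "+")],
        "db2": [PutativeTag("CATGAA", "db2", "g7", 0, "+"),
                PutativeTag("CATGTT", "db2", "g8", 0, "+")],
    }
    return build_tag_database(streams, CATG, 6)


def budget(m=1):
    return SearchBudget(max_mismatch=m, prefix_len=4)


class TestAnnotateRead:
    def test_single_exact_hit_in_two_sources(self):
        db = small_db()
        root = build_trie(db)
        rec = annotate_read(QueryRead("r1", "CATGAA"), db, root, budget())
        assert rec.hits["db1"].exact_ids == ["tx1"]
        assert rec.hits["db1"].exact_n == 1
        assert rec.hits["db2"].exact_ids == ["g7"]
        assert rec.hits["db1"].degenerate_ids == []
        assert rec.hits["db2"].degenerate_ids == []

    def test_no_hit_record_still_emitted(self):
        db = small_db()
        root = build_trie(db)
        rec = annotate_read(QueryRead("r1", "CATGCC"), db, root, budget(0))
        assert not rec.has_any_hit()
        assert rec.flag is None
        assert set(rec.hits) == {"db1", "db2"}

    def test_degenerate_bucket_for_one_mismatch(self):
        db = small_db()
        root = build_trie(db)
        rec = annotate_read(QueryRead("r1", "CATGAT"), db, root, budget(1))
        # 1 mismatch from CATGAA, 1 from CATGTT: both degenerate
        assert rec.hits["db1"].degenerate_ids == ["tx1"]
        assert rec.hits["db2"].degenerate_ids == ["g7", "g8"]
        assert rec.hits["db2"].exact_ids == []

    def test_exact_takes_precedence_per_id(self):
        # one source id carries two tags; a read hitting one exactly and the
        # other degenerately reports the id as exact only
        streams = {"db1": [PutativeTag("CATGAA", "db1", "tx1", 0, "+"),
                           PutativeTag("CATGAT", "db1", "tx1", 50, "+")]}
        db = build_tag_database(streams, CATG, 6)
        root = build_trie(db)
        rec = annotate_read(QueryRead("r1", "CATGAA"), db, root, budget(1))
        assert rec.hits["db1"].exact_ids == ["tx1"]
        assert rec.hits["db1"].degenerate_ids == []

    def test_overlength_read_flagged_unmapped(self, caplog):
        db = small_db()
        root = build_trie(db)
        with caplog.at_level("WARNING"):
            rec = annotate_read(QueryRead("r1", "CATGAAAAAA"), db, root, budget())
        assert rec.flag == "overlength"
        assert not rec.has_any_hit()
        assert any("longer" in m for m in caplog.messages)

    def test_reported_ids_are_brute_force_auditable(self):
        rng = np.random.default_rng(12)
        seqs = sorted({"CATG" + "".join("ACGT"[b] for b in rng.integers(0, 4, 6))
                       for _ in range(80)})
        streams = {"db1": [PutativeTag(s, "db1", f"tx{i}", 0, "+")
                           for i, s in enumerate(seqs)]}
        db = build_tag_database(streams, CATG, 10)
        root = build_trie(db)
        id_of = {s: f"tx{i}" for i, s in enumerate(seqs)}
        for _ in range(30):
            q = "CATG" + "".join("ACGT"[b] for b in rng.integers(0, 4, 6))
            rec = annotate_read(QueryRead("q", q), db, root, budget(1))
            reported = set(rec.hits["db1"].exact_ids) | set(rec.hits["db1"].degenerate_ids)
            expected = set()
            for s in seqs:
                mm = sum(a != b for a, b in zip(q, s))
                pmm = sum(a != b for a, b in zip(q[:4], s[:4]))
                if mm <= 1 and pmm <= 1:
                    expected.add(id_of[s])
            assert reported == expected


class TestAnnotateAll:
    def test_empty_input(self):
        db = small_db()
        root = build_trie(db)
        summary = MappingSummary()
        records = list(annotate_all([], db, root, budget(), summary=summary))
        assert records == []
        assert summary.n_reads == 0 and summary.pct(summary.reads_exact) == 0.0

    def test_error_free_reads_from_every_tag_all_exact(self):
        db = small_db()
        root = build_trie(db)
        reads, _ = make_reads(db, n_reads=len(db), mode="exact", seed=0)
        summary = MappingSummary()
        list(annotate_all(reads, db, root, budget(), summary=summary))
        assert summary.reads_exact == summary.n_reads

    def test_summary_fractions_on_mixed_fixture(self):
        # 70 exact, 20 one-substitution, 10 brute-force-verified decoys
        rng = np.random.default_rng(3)
        seqs = sorted({"CATG" + "".join("ACGT"[b] for b in rng.integers(0, 4, 12))
                       for _ in range(70)})
        streams = {"db1": [PutativeTag(s, "db1", f"tx{i}", 0, "+")
                           for i, s in enumerate(seqs)]}
        db = build_tag_database(streams, CATG, 16)
        root = build_trie(db)
        exact_reads, _ = make_reads(db, n_reads=70, mode="exact", seed=1)
        sub_reads, _ = make_reads(db, n_reads=20, mode="one_substitution", seed=2)
        decoys, _ = make_reads(db, n_reads=0, n_decoys=10, decoy_budget=1, seed=3)
        summary = MappingSummary()
        list(annotate_all(exact_reads + sub_reads + decoys, db, root, budget(1),
                          summary=summary))
        assert summary.n_reads == 100
        assert summary.pct(summary.reads_exact) == 70.0
        assert summary.pct(summary.reads_degenerate_only) == 20.0
        assert summary.pct(summary.reads_unmapped) == 10.0


class TestOutputTable:
    def test_layout_and_empty_cells(self):
        db = small_db()
        root = build_trie(db)
        rec = annotate_read(QueryRead("r1", "CATGAA", 3), db, root, budget())
        assert header_line(db.source_labels).split("\t") == [
            "#read_id", "count", "sequence",
            "db1_exact_ids", "db1_exact_n", "db1_mm_ids", "db1_mm_n",
            "db2_exact_ids", "db2_exact_n", "db2_mm_ids", "db2_mm_n", "flag",
        ]
        row = format_record(rec, db.source_labels).split("\t")
        assert row == ["r1", "3", "CATGAA", "tx1", "1", "-", "0",
                       "g7", "1", "-", "0", "-"]

    def test_display_cap_truncates_ids_not_counts(self):
        streams = {"db1": [PutativeTag("CATGAA", "db1", f"tx{i:03d}", 0, "+")
                           for i in range(40)]}
        db = build_tag_database(streams, CATG, 6)
        root = build_trie(db)
        rec = annotate_read(QueryRead("r1", "CATGAA"), db, root, budget())
        row = format_record(rec, ["db1"], display_cap=25).split("\t")
        ids_cell, n_cell = row[3], row[4]
        assert n_cell == "40"
        assert ids_cell.endswith("...")
        assert len(ids_cell.split(",")) == 26  # 25 ids + marker

    def test_write_annotation_deterministic_bytes(self):
        db = small_db()
        root = build_trie(db)
        reads = [QueryRead("r1", "CATGAA", 2), QueryRead("r2", "CATGTT", 1)]
        outputs = []
        for _ in range(2):
            buf = io.StringIO()
            write_annotation(
                annotate_all(reads, db, root, budget()), buf, db.source_labels
            )
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]
        assert outputs[0].startswith("#read_id\t")
        assert len(outputs[0].splitlines()) == 3
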