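"""Map experimental tags against db_tags and emit the parsed annotation.

Each unique experimental tag is searched against the trie once; the hit
entries' provenance is then unrolled into per-source buckets: *exact*
(0 mismatches) and *degenerate* (>= 1 mismatch, up to the budget).  Counts
are distinct source sequence ids per source database — the number of
reference entries a read matches, which is what a user needs to judge the
reliability of a mapping.  Within one source, an id hit both exactly and
degenerately (via different database tags) is reported only as exact.

The output is a rectangular tab-delimited table, one row per unique read,
with all sources side by side, so no post-processing or file juggling is
needed to compare a conservative transcript hit against a genomic one.  A
read with no hit anywhere still gets a row: a transcript-database miss with
a genomic hit is the signature of a potential novel transcript, so absence
is informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .sequence_io import QueryRead, _open_text
from .tag_db import TagDatabase
from .trie import SearchBudget, TrieNode, search_mismatch

logger = logging.getLogger(__name__)

DEFAULT_DISPLAY_CAP = 25
TRUNCATION_MARKER = "..."


@dataclass
class SourceHits:
    """Exact and degenerate hits of one read in one source database."""

    exact_ids: list[str] = field(default_factory=list)
    degenerate_ids: list[str] = field(default_factory=list)

    @property
    def exact_n(self) -> int:
        return len(self.exact_ids)

    @property
    def degenerate_n(self) -> int:
        return len(self.degenerate_ids)


@dataclass
class AnnotationRecord:
    """Per-read result row across all source databases."""

    read_id: str
    read_count: int
    sequence: str
    hits: dict[str, SourceHits]
    flag: str | None = None  # "overlength" for reads longer than L

    def has_exact_hit(self) -> bool:
        return any(h.exact_ids for h in self.hits.values())

    def has_any_hit(self) -> bool:
        return any(h.exact_ids or h.degenerate_ids for h in self.hits.values())


@dataclass
class MappingSummary:
    """Count-weighted mapping statistics over a whole run."""

    n_unique: int = 0
    n_reads: int = 0
    reads_exact: int = 0
    reads_degenerate_only: int = 0
    reads_unmapped: int = 0

    def pct(self, n: int) -> float:
        return 100.0 * n / self.n_reads if self.n_reads else 0.0


def annotate_read(
    read: QueryRead, db: TagDatabase, root: TrieNode, budget: SearchBudget
) -> AnnotationRecord:
    """Search one unique read and bucket its hits per source database.

    A read longer than the database tag length cannot be mapped (trimming
    is upstream's job) and is recorded as unmapped with an "overlength"
    flag.  A read shorter than the site cannot carry the site and is
    likewise recorded unmapped.
    """
    hits = {label: SourceHits() for label in db.source_labels}
    record = AnnotationRecord(
        read_id=read.id, read_count=read.count, sequence=read.sequence, hits=hits
    )
    if len(read.sequence) > db.L:
        record.flag = "overlength"
        logger.warning(
            "read %s is %d bp, longer than the %d bp database tags; "
            "left unmapped (trim the read or rebuild the database)",
            read.id, len(read.sequence), db.L,
        )
        return record
    if len(read.sequence) < db.site.k:
        record.flag = "short"
        return record
    exact: dict[str, set[str]] = {label: set() for label in db.source_labels}
    degenerate: dict[str, set[str]] = {label: set() for label in db.source_labels}
    for entry, mismatches in search_mismatch(root, read.sequence, budget, db.L):
        bucket = exact if mismatches == 0 else degenerate
        for label, by_id in entry.provenance.items():
            bucket[label].update(by_id)
    for label in db.source_labels:
        hits[label].exact_ids = sorted(exact[label])
        # exact takes precedence: one transcript is never reported twice
        hits[label].degenerate_ids = sorted(degenerate[label] - exact[label])
    return record


def annotate_all(
    reads: Iterable[QueryRead],
    db: TagDatabase,
    root: TrieNode,
    budget: SearchBudget,
    summary: MappingSummary | None = None,
) -> Iterator[AnnotationRecord]:
    """Annotate every read in input order; log summary statistics at the end.

    Pass a :class:`MappingSummary` to also receive the statistics
    programmatically (it is filled in place as records are consumed).
    """
    if summary is None:
        summary = MappingSummary()
    for read in reads:
        record = annotate_read(read, db, root, budget)
        summary.n_unique += 1
        summary.n_reads += read.count
        if record.has_exact_hit():
            summary.reads_exact += read.count
        elif record.has_any_hit():
            summary.reads_degenerate_only += read.count
        else:
            summary.reads_unmapped += read.count
        yield record
    logger.info(
        "annotated %d unique tags (%d reads): %.2f%% exact, "
        "%.2f%% degenerate-only, %.2f%% unmapped",
        summary.n_unique,
        summary.n_reads,
        summary.pct(summary.reads_exact),
        summary.pct(summary.reads_degenerate_only),
        summary.pct(summary.reads_unmapped),
    )


def _format_ids(ids: list[str], display_cap: int) -> str:
    if not ids:
        return "-"
    if display_cap and len(ids) > display_cap:
        return ",".join(ids[:display_cap]) + "," + TRUNCATION_MARKER
    return ",".join(ids)


def header_line(source_labels: list[str]) -> str:
    cols = ["#read_id", "count", "sequence"]
    for label in source_labels:
        cols += [f"{label}_exact_ids", f"{label}_exact_n", f"{label}_mm_ids", f"{label}_mm_n"]
    cols.append("flag")
    return "\t".join(cols)


def format_record(
    record: AnnotationRecord,
    source_labels: list[str],
    display_cap: int = DEFAULT_DISPLAY_CAP,
) -> str:
    """One output row.  Id lists are comma-separated and may be truncated
    for display; the count columns always carry the true totals."""
    cols = [record.read_id, str(record.read_count), record.sequence]
    for label in source_labels:
        hit = record.hits[label]
        cols += [
            _format_ids(hit.exact_ids, display_cap),
            str(hit.exact_n),
            _format_ids(hit.degenerate_ids, display_cap),
            str(hit.degenerate_n),
        ]
    cols.append(record.flag or "-")
    return "\t".join(cols)


def write_annotation(
    records: Iterable[AnnotationRecord],
    path_or_handle: str | Path | IO[str],
    source_labels: list[str],
    display_cap: int = DEFAULT_DISPLAY_CAP,
) -> None:
    """Write the tab-delimited annotation table (deterministic byte output)."""
    if hasattr(path_or_handle, "write"):
        out = path_or_handle
        close = False
    else:
        out = _open_text(path_or_handle, "wt")
        close = True
    try:
        out.write(header_line(source_labels) + "\n")
        for record in records:
            out.write(format_record(record, source_labels, display_cap) + "\n")
    finally:
        if close:
            out.close()
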