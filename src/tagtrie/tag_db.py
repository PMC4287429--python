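"""Sort, merge and persist the unified putative-tag database (db_tags).

Tags extracted from up to three reference sources (typically a conservative
transcript set, a liberal transcript set, and genomic DNA) are merged into a
single store keyed by tag sequence.  Each distinct sequence keeps full
provenance: which source databases it occurs in, in which sequence records,
at which positions and strands.  Entries are kept strictly sorted in plain
lexicographic order (A<C<G<T as bytes), which makes merge-by-adjacency and
trie construction deterministic.

The on-disk format is a versioned, headered, tab-delimited text file —
inspectable with standard tools, optionally gzipped.  The header records
site, tag length and source labels so a cached file is only reused when it
matches the requested build.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from . import sequence_io
from .errors import ConfigError, ParseError
from .tag_extraction import PutativeTag, SiteSpec

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

# provenance: source_db -> source_id -> sorted list of (position, strand)
Provenance = dict[str, dict[str, list[tuple[int, str]]]]


@dataclass
class TagEntry:
    """One distinct tag sequence with merged provenance across sources."""

    sequence: str
    provenance: Provenance

    def source_ids(self, source_db: str) -> list[str]:
        """Distinct source sequence ids carrying this tag, sorted."""
        return sorted(self.provenance.get(source_db, ()))

    def n_occurrences(self) -> int:
        return sum(
            len(positions)
            for by_id in self.provenance.values()
            for positions in by_id.values()
        )


@dataclass
class TagDatabase:
    """Sorted, deduplicated collection of putative tags (db_tags)."""

    site: SiteSpec
    L: int
    source_labels: list[str]
    entries: list[TagEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> list[str]:
        return [e.sequence for e in self.entries]

    def total_occurrences(self) -> int:
        return sum(e.n_occurrences() for e in self.entries)


def build_tag_database(
    tag_streams: Mapping[str, Iterable[PutativeTag]],
    spec: SiteSpec,
    L: int,
) -> TagDatabase:
    """Merge per-source tag streams into one sorted, unique database.

    ``tag_streams`` maps each source label to its stream of putative tags
    (the label order fixes the output column order downstream).  A tag
    occurring several times in one source sequence contributes a single
    source_id with all its (position, strand) pairs.  A stream containing a
    tag of the wrong length is a fatal configuration error: all sources must
    be extracted with the same tag length.
    """
    by_seq: dict[str, Provenance] = {}
    for label, stream in tag_streams.items():
        for tag in stream:
            if len(tag.sequence) != L:
                raise ConfigError(
                    f"source {label!r}: tag {tag.sequence!r} has length "
                    f"{len(tag.sequence)}, expected {L} — all sources must use the same tag length"
                )
            prov = by_seq.setdefault(tag.sequence, {})
            occs = prov.setdefault(label, {}).setdefault(tag.source_id, [])
            occs.append((tag.position, tag.strand))
    entries = []
    for seq in sorted(by_seq):
        prov = by_seq[seq]
        for by_id in prov.values():
            for occs in by_id.values():
                occs.sort()
        entries.append(TagEntry(sequence=seq, provenance=prov))
    db = TagDatabase(site=spec, L=L, source_labels=list(tag_streams), entries=entries)
    logger.info(
        "merged %d distinct tags (%d occurrences) from sources %s",
        len(db), db.total_occurrences(), ",".join(db.source_labels),
    )
    return db


def save_db(db: TagDatabase, path: str | Path) -> None:
    """Write db_tags as headered tab-delimited text (gzip by extension)."""
    with sequence_io._open_text(path, "wt") as out:
        out.write(f"# tagtrie db_tags format_version={FORMAT_VERSION}\n")
        out.write(f"# site={db.site.site}\n")
        out.write(f"# L={db.L}\n")
        out.write(f"# sources={','.join(db.source_labels)}\n")
        for entry in db.entries:
            for label in db.source_labels:
                by_id = entry.provenance.get(label)
                if not by_id:
                    continue
                for source_id in sorted(by_id):
                    for position, strand in by_id[source_id]:
                        out.write(
                            f"{entry.sequence}\t{label}\t{source_id}\t{position}\t{strand}\n"
                        )


def read_db_header(path: str | Path) -> dict[str, str]:
    """Parse the '#' header of a db_tags file into a key/value dict."""
    header: dict[str, str] = {}
    with sequence_io._open_text(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    key, _, value = token.partition("=")
                    header[key] = value
    for key in ("format_version", "site", "L", "sources"):
        if key not in header:
            raise ParseError(f"{path}: db_tags header is missing {key!r}")
    return header


def load_db(path: str | Path) -> TagDatabase:
    """Load a db_tags file written by :func:`save_db` (lossless round trip)."""
    path = Path(path)
    header = read_db_header(path)
    try:
        version = int(header["format_version"])
        L = int(header["L"])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed db_tags header: {exc}") from exc
    if version != FORMAT_VERSION:
        raise ParseError(f"{path}: unsupported db_tags format version {version}")
    spec = SiteSpec(header["site"])
    source_labels = [s for s in header["sources"].split(",") if s]
    by_seq: dict[str, Provenance] = {}
    order: list[str] = []
    with sequence_io._open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 tab-delimited fields")
            seq, label, source_id, position, strand = fields
            if len(seq) != L or strand not in "+-" or label not in source_labels:
                raise ParseError(f"{path}:{lineno}: corrupt db_tags record")
            try:
                pos = int(position)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {position!r}") from exc
            if seq not in by_seq:
                by_seq[seq] = {}
                order.append(seq)
            by_seq[seq].setdefault(label, {}).setdefault(source_id, []).append((pos, strand))
    if order != sorted(order):
        raise ParseError(f"{path}: db_tags entries are not sorted")
    entries = [TagEntry(sequence=seq, provenance=by_seq[seq]) for seq in order]
    return TagDatabase(site=spec, L=L, source_labels=source_labels, entries=entries)


def cache_matches(path: str | Path, spec: SiteSpec, L: int) -> bool:
    """True if an existing db_tags file was built with this site and L.

    A missing or unreadable file, or a header recording a different site or
    tag length, means the cache cannot be reused and the database must be
    rebuilt.
    """
    path = Path(path)
    if not path.exists():
        return False
    try:
        header = read_db_header(path)
        ok = header["site"] == spec.site and int(header["L"]) == L
    except (ParseError, ValueError, OSError):
        logger.warning("%s: unreadable db_tags header; cache ignored", path)
        return False
    if not ok:
        logger.info(
            "%s: cached db_tags (site=%s, L=%s) does not match request "
            "(site=%s, L=%d); rebuilding",
            path, header.get("site"), header.get("L"), spec.site, L,
        )
    return ok
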