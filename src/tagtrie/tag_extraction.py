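"""Scan reference sequences for restriction sites and emit putative tags.

Every DGE tag starts at a restriction-enzyme recognition site (the *site*,
e.g. NlaIII's CATG), so the universe of tags a reference database can
produce is enumerable: every window whose first k bases lie within Hamming
distance 1 of the site yields up to two fixed-length tags, one per strand.
The single tolerated site mismatch rescues restriction sites that exist in
the sample but are mutated in the reference (a common situation in highly
polymorphic genomes): the stored tag carries the reference's variant site,
and an experimental tag carrying the canonical site finds it later through
a one-mismatch search.

Coordinates are 0-based with half-open slices.  ``position`` is always the
offset of the site's first base on the forward strand, for both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from .errors import ConfigError
from .sequence_io import SeqRecord, read_fasta, reverse_complement

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SiteSpec:
    """The enzyme recognition sequence and the scan mismatch tolerance.

    ``max_site_mismatch_scan`` is fixed at 1: database scanning always
    tolerates exactly one mismatch in the site, independently of the search
    budget applied later at query time.
    """

    site: str
    max_site_mismatch_scan: int = field(default=1, init=False)

    def __post_init__(self) -> None:
        if len(self.site) < 2:
            raise ConfigError(f"site {self.site!r} is too short (need >= 2 bases)")
        bad = set(self.site) - _ACGT
        if bad:
            raise ConfigError(f"site {self.site!r} contains non-ACGT characters {sorted(bad)}")

    @property
    def k(self) -> int:
        return len(self.site)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.site) == self.site


class PutativeTag(NamedTuple):
    """One candidate tag read off a reference sequence, with provenance."""

    sequence: str
    source_db: str
    source_id: str
    position: int
    strand: str


def _window_mismatches(window: str, site: str, limit: int) -> int:
    """Hamming distance window vs site, capped at limit+1 for early exit.

    Any non-ACGT character in the window counts as a mismatch.
    """
    mm = 0
    for a, b in zip(window, site):
        if a != b or a not in _ACGT:
            mm += 1
            if mm > limit:
                break
    return mm


def find_site_occurrences(sequence: str, spec: SiteSpec, motif: str | None = None) -> list[int]:
    """Every 0-based position whose k-window is within Hamming 1 of the site.

    Overlapping occurrences are all reported, in increasing order.  A
    sequence shorter than the site yields an empty list.  ``motif``
    overrides the scanned motif (used internally for non-palindromic
    reverse-strand scans) but keeps the same tolerance.
    """
    motif = spec.site if motif is None else motif
    limit = spec.max_site_mismatch_scan
    k = len(motif)
    return [
        p
        for p in range(len(sequence) - k + 1)
        if _window_mismatches(sequence[p : p + k], motif, limit) <= limit
    ]


def extract_tags_at(
    record: SeqRecord,
    p: int,
    spec: SiteSpec,
    L: int,
    source_db: str,
    strands: str = "+-",
) -> list[PutativeTag]:
    """Tags anchored at site occurrence ``p``: 0, 1 or 2 of them.

    Forward tag: ``sequence[p : p+L]``, emitted only when the site lies at
    least L bases from the 3' end — otherwise the real read would run into
    poly-A/adapter and the database deliberately omits it.  Reverse tag:
    reverse complement of ``sequence[p-(L-k) : p+k]`` (the site plus the
    bases immediately upstream), emitted only when ``p >= L-k``.  A window
    containing any non-ACGT character is suppressed: the tag alphabet is
    strictly {A,C,G,T}.
    """
    k = spec.k
    seq = record.sequence
    out: list[PutativeTag] = []
    if "+" in strands and p + L <= len(seq):
        fwd = seq[p : p + L]
        if _ACGT.issuperset(fwd):
            out.append(PutativeTag(fwd, source_db, record.id, p, "+"))
    if "-" in strands and p >= L - k:
        window = seq[p - (L - k) : p + k]
        if _ACGT.issuperset(window):
            out.append(PutativeTag(reverse_complement(window), source_db, record.id, p, "-"))
    return out


def scan_record(record: SeqRecord, spec: SiteSpec, L: int, source_db: str) -> Iterator[PutativeTag]:
    """All putative tags from one reference sequence, both strands.

    The sequence is scanned on one strand only.  For a reverse-palindromic
    site every occurrence is simultaneously a reverse-strand site, so one
    scan feeds both strands.  For a non-palindromic site a second scan for
    the reverse complement of the site (same one-mismatch tolerance)
    supplies the reverse-strand tags.
    """
    if L < spec.k:
        raise ConfigError(f"tag length {L} is shorter than the site ({spec.k} bp)")
    if spec.is_palindromic:
        for p in find_site_occurrences(record.sequence, spec):
            yield from extract_tags_at(record, p, spec, L, source_db)
    else:
        for p in find_site_occurrences(record.sequence, spec):
            yield from extract_tags_at(record, p, spec, L, source_db, strands="+")
        rc_site = reverse_complement(spec.site)
        for p in find_site_occurrences(record.sequence, spec, motif=rc_site):
            yield from extract_tags_at(record, p, spec, L, source_db, strands="-")


def scan_database(
    fasta_path: str | Path, spec: SiteSpec, L: int, source_db: str
) -> Iterator[PutativeTag]:
    """Stream every putative tag from a FASTA reference database."""
    n_tags = 0
    for record in read_fasta(fasta_path):
        for tag in scan_record(record, spec, L, source_db):
            n_tags += 1
            yield tag
    logger.info("%s [%s]: extracted %d putative tags", fasta_path, source_db, n_tags)


def scan_records(
    records: Iterable[SeqRecord], spec: SiteSpec, L: int, source_db: str
) -> Iterator[PutativeTag]:
    """As :func:`scan_database` but over in-memory records."""
    for record in records:
        yield from scan_record(record, spec, L, source_db)
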