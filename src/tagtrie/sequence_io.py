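"""Reading, writing and collapsing of FASTA/FASTQ sequence data.

DGE (digital gene expression) experiments produce single-end reads that all
begin at a restriction site, so many raw reads are byte-identical.  The
conventional way to present such data to a mapper is *collapsed*: one FASTQ
entry per distinct sequence, with the number of raw reads it represents
encoded in the read name.  This module fixes that convention as a terminal
``-<integer>`` suffix on the name (``tag1-37`` means 37 identical reads); a
name without a parseable suffix means a count of one.

Both FASTA and FASTQ are accepted plain or gzip-compressed (by ``.gz``
extension).  Base qualities are read and discarded — the mapping method is
purely sequence-based.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import AlphabetError, ParseError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_COUNT_SUFFIX = re.compile(r"^(?P<stem>.*)-(?P<count>\d+)$")


@dataclass(frozen=True)
class SeqRecord:
    """One reference sequence: id (first header token), description, bases."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"invalid sequence id: {self.id!r}")
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class QueryRead:
    """One unique experimental tag sequence with its collapsed read count."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ParseError(f"read {self.id!r} has non-positive count {self.count}")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def reverse_complement(s: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N.

    Raises :class:`AlphabetError` naming the first character outside the
    alphabet.
    """
    for c in s:
        if c not in "ACGTN":
            raise AlphabetError(f"cannot complement character {c!r}")
    return s.translate(_COMPLEMENT)[::-1]


def _filtered_fasta_lines(handle: IO[str], path: Path) -> Iterator[str]:
    # UniGene-style dumps intersperse comment lines that are not valid FASTA;
    # drop them before Biopython sees the stream.
    for lineno, line in enumerate(handle, 1):
        stripped = line.strip()
        if stripped and not stripped.startswith(">") and stripped[0] in "#;":
            logger.warning("%s:%d: skipping non-FASTA comment line", path, lineno)
            continue
        yield line


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    """Yield :class:`SeqRecord` per FASTA entry, in file order.

    Multi-line sequences are concatenated and uppercased.  Stray comment
    lines (``#``/``;``) are skipped with a warning; entries with an empty
    sequence are skipped with a warning.  A missing file is a fatal I/O
    error.
    """
    path = Path(path)
    with _open_text(path) as handle:
        for header, seq in SimpleFastaParser(_filtered_fasta_lines(handle, path)):
            parts = header.split(None, 1)
            if not parts:
                logger.warning("%s: skipping record with empty header", path)
                continue
            seq = "".join(seq.split()).upper()
            if not seq:
                logger.warning("%s: skipping record %r with empty sequence", path, parts[0])
                continue
            yield SeqRecord(
                id=parts[0],
                description=parts[1] if len(parts) > 1 else "",
                sequence=seq,
            )


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def parse_read_name(name: str) -> tuple[str, int]:
    """Split a collapsed read name into (stem, count); count=1 if no suffix."""
    m = _COUNT_SUFFIX.match(name)
    if m:
        return m.group("stem"), int(m.group("count"))
    return name, 1


def read_fastq(path: str | Path) -> Iterator[QueryRead]:
    """Yield :class:`QueryRead` per 4-line FASTQ record.

    The collapsed-read count is parsed from the name suffix; quality strings
    are discarded.  A truncated record is a fatal parse error naming the
    offending line.
    """
    path = Path(path)
    n_records = 0
    with _open_text(path) as handle:
        try:
            for title, seq, _qual in FastqGeneralIterator(handle):
                n_records += 1
                name = title.split(None, 1)[0]
                stem, count = parse_read_name(name)
                yield QueryRead(id=stem, sequence=seq.upper(), count=count)
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed FASTQ near line {n_records * 4 + 1}: {exc}"
            ) from exc


def write_fastq(reads: Iterable[QueryRead], path: str | Path) -> None:
    """Write reads with the count encoded in the name and constant qualities."""
    with _open_text(path, "wt") as out:
        for read in reads:
            name = read.id
            if parse_read_name(name)[1] != read.count:
                name = f"{name}-{read.count}"
            out.write(f"@{name}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def collapse_reads(reads: Iterable[QueryRead]) -> list[QueryRead]:
    """Merge identical sequences, summing counts.

    The output id is the first-seen id for each sequence, re-suffixed with
    the total count.  Output is sorted by descending count, ties broken by
    sequence, so the most abundant tags come first.
    """
    first_id: dict[str, str] = {}
    totals: dict[str, int] = {}
    for read in reads:
        if read.sequence not in totals:
            first_id[read.sequence] = read.id
            totals[read.sequence] = 0
        totals[read.sequence] += read.count
    collapsed = [
        QueryRead(id=f"{first_id[seq]}-{n}", sequence=seq, count=n)
        for seq, n in totals.items()
    ]
    collapsed.sort(key=lambda r: (-r.count, r.sequence))
    return collapsed
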