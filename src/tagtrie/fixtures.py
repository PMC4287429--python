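"""Synthetic reference and read generators with exact ground truth.

Every other module is testable without downloads: this module plants
restriction sites into random background sequence and records exactly which
tags extraction must produce, then samples reads from a built tag database
with controlled errors and records exactly where each read came from.

The generator emulates the *statistical structure* the mapper depends on —
site-anchored fixed-length tags, reference site polymorphisms (planted
one-mismatch sites), boundary sites too close to a sequence end to yield a
forward tag, and collapsed reads with counts — not a realistic
transcriptome (no expression model, isoforms, or quality variation; decoy
reads stand in for contamination).  Backgrounds are cleaned by redrawing
any window that strays within one mismatch of the site, so the planted
truth table is exhaustive, not merely expected.

Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FixtureError
from .sequence_io import QueryRead, SeqRecord, reverse_complement, write_fasta, write_fastq
from .tag_db import TagDatabase
from .tag_extraction import PutativeTag, SiteSpec, find_site_occurrences

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic reference/read set.

    Planted sites are spaced at least 2L-k apart so their tag footprints
    never overlap, and kept at least L-k from the start and L from the end
    of each sequence unless ``allow_boundary_sites`` plants one extra site
    in each boundary zone (suppressing one strand's tag, which is exactly
    the behaviour the boundary rules must exhibit).
    """

    site: str = "CATG"
    L: int = 20
    n_sequences: int = 3
    length_range: tuple[int, int] = (300, 600)
    sites_per_sequence: int = 2
    mutated_sites_per_sequence: int = 0
    allow_boundary_sites: bool = False
    clean_background: bool = True
    error_rate: float = 0.0
    errors_non_prefix_only: bool = True
    seed: int = 0

    def site_spec(self) -> SiteSpec:
        return SiteSpec(self.site)


@dataclass
class ReadTruth:
    """Where one generated read came from and what was done to it."""

    read_id: str
    sequence: str
    origin_sequence: str | None  # db tag the read was drawn from; None = decoy
    n_substitutions: int = 0
    substitution_positions: list[int] = field(default_factory=list)


@dataclass
class ReferenceFixture:
    """Generated references plus the exhaustive expected-tag table."""

    records: dict[str, list[SeqRecord]]
    expected_tags: list[PutativeTag]
    fasta_paths: dict[str, Path] = field(default_factory=dict)


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _plant_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, min_gap: int
) -> list[int]:
    """n positions in [lo, hi], pairwise at least min_gap apart."""
    if n == 0:
        return []
    span = hi - lo - (n - 1) * min_gap
    if span < 0:
        raise FixtureError(
            f"cannot place {n} sites with spacing {min_gap} in [{lo}, {hi}]"
        )
    offsets = np.sort(rng.integers(0, span + 1, size=n))
    return [int(lo + off + i * min_gap) for i, off in enumerate(offsets)]


def _mutate_site(rng: np.random.Generator, site: str) -> str:
    pos = int(rng.integers(0, len(site)))
    alternatives = [b for b in "ACGT" if b != site[pos]]
    return site[:pos] + alternatives[int(rng.integers(0, 3))] + site[pos + 1 :]


def _clean_background(
    rng: np.random.Generator,
    seq: np.ndarray,
    spec: SiteSpec,
    planted: set[int],
    max_rounds: int = 500,
) -> None:
    """Redraw bases until the only near-site windows are the planted ones.

    Bases inside planted site windows are protected; a spurious window
    whose free bases cannot be redrawn (fully inside planted windows) makes
    the fixture parameters infeasible.
    """
    k = spec.k
    protected = {i for p in planted for i in range(p, p + k)}
    motifs = [spec.site]
    if not spec.is_palindromic:
        motifs.append(reverse_complement(spec.site))
    for _ in range(max_rounds):
        text = seq.tobytes().decode()
        spurious = {
            p
            for motif in motifs
            for p in find_site_occurrences(text, spec, motif=motif)
            if p not in planted
        }
        if not spurious:
            return
        for p in spurious:
            free = [i for i in range(p, p + k) if i not in protected]
            if not free:
                raise FixtureError(
                    f"spurious site at {p} overlaps planted sites and cannot be removed"
                )
            seq[free] = _random_bases(rng, len(free))
    raise FixtureError("background cleaning did not converge; sequence too dense with sites")


def _generate_sequence(
    rng: np.random.Generator, spec: FixtureSpec
) -> tuple[str, list[int]]:
    """One background sequence with planted sites; returns (seq, positions)."""
    site_spec = spec.site_spec()
    k, L = site_spec.k, spec.L
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    min_gap = 2 * L - k
    lo, hi = L - k, length - L
    boundary: list[int] = []
    if spec.allow_boundary_sites:
        if length < 5 * L:
            raise FixtureError("sequences too short for boundary sites; increase length_range")
        # one site too close to the start (reverse tag suppressed) and one
        # too close to the end (forward tag suppressed)
        boundary.append(int(rng.integers(0, L - k)))
        boundary.append(int(rng.integers(length - L + 1, length - k + 1)))
        lo = boundary[0] + min_gap
        hi = boundary[1] - min_gap
    n_interior = spec.sites_per_sequence + spec.mutated_sites_per_sequence
    interior = _plant_positions(rng, lo, hi, n_interior, min_gap)
    positions = sorted(boundary + interior)
    # the mutated sites are drawn from the interior ones
    mutated = set(
        interior[i] for i in rng.choice(
            len(interior), size=spec.mutated_sites_per_sequence, replace=False
        )
    ) if spec.mutated_sites_per_sequence else set()
    seq = _random_bases(rng, length)
    for p in positions:
        motif = _mutate_site(rng, spec.site) if p in mutated else spec.site
        seq[p : p + k] = np.frombuffer(motif.encode(), dtype=np.uint8)
    if spec.clean_background:
        _clean_background(rng, seq, site_spec, set(positions))
    return seq.tobytes().decode(), positions


def _expected_tags_at(
    text: str, p: int, site_spec: SiteSpec, L: int, source_db: str, source_id: str
) -> list[PutativeTag]:
    # mirrors the extraction boundary rules; reverse tags only exist for
    # palindromic sites because the generator plants forward-strand motifs
    k = site_spec.k
    out = []
    if p + L <= len(text):
        out.append(PutativeTag(text[p : p + L], source_db, source_id, p, "+"))
    if site_spec.is_palindromic and p >= L - k:
        out.append(
            PutativeTag(
                reverse_complement(text[p - (L - k) : p + k]), source_db, source_id, p, "-"
            )
        )
    return out


def make_reference_set(
    spec: FixtureSpec,
    labels: tuple[str, ...] = ("db1", "db2", "db3"),
    out_dir: str | Path | None = None,
) -> ReferenceFixture:
    """Generate one FASTA reference per label plus the expected-tag table.

    With a clean background the table is exhaustive: scanning the FASTA
    must reproduce it exactly — sequences, positions and strands.
    """
    rng = np.random.default_rng(spec.seed)
    site_spec = spec.site_spec()
    records: dict[str, list[SeqRecord]] = {}
    expected: list[PutativeTag] = []
    for label in labels:
        recs = []
        for i in range(spec.n_sequences):
            text, positions = _generate_sequence(rng, spec)
            rec_id = f"{label}_seq{i + 1}"
            recs.append(SeqRecord(id=rec_id, description="synthetic", sequence=text))
            for p in positions:
                expected.extend(
                    _expected_tags_at(text, p, site_spec, spec.L, label, rec_id)
                )
        records[label] = recs
    fixture = ReferenceFixture(records=records, expected_tags=expected)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, recs in records.items():
            path = out_dir / f"{label}.fasta"
            write_fasta(recs, path)
            fixture.fasta_paths[label] = path
    return fixture


def _capped_distance(query: str, target: str, k: int) -> int | None:
    """Hamming distance under the prefix cap; None if > 1 prefix mismatch."""
    mm = pmm = 0
    for i, (a, b) in enumerate(zip(query, target)):
        if a != b:
            mm += 1
            if i < k:
                pmm += 1
                if pmm > 1:
                    return None
    return mm


def make_reads(
    db: TagDatabase,
    n_reads: int,
    mode: str = "exact",
    n_decoys: int = 0,
    decoy_budget: int = 1,
    seed: int = 0,
    error_rate: float = 0.0,
    non_prefix_only: bool = True,
    count_range: tuple[int, int] = (1, 1),
    out_path: str | Path | None = None,
) -> tuple[list[QueryRead], list[ReadTruth]]:
    """Sample reads from database tags with controlled errors, plus decoys.

    Modes: ``exact`` — verbatim tags; ``one_substitution`` — exactly one
    substitution per read (at a non-prefix position unless
    ``non_prefix_only`` is off); ``random`` — independent per-base
    substitutions at ``error_rate``.  Reads cycle through the database
    entries, so ``n_reads >= len(db)`` covers every tag.  Decoys are random
    site-prefixed sequences verified by brute force to lie more than
    ``decoy_budget`` capped mismatches from every database tag.
    """
    if len(db) == 0:
        raise FixtureError("cannot sample reads from an empty tag database")
    rng = np.random.default_rng(seed)
    k = db.site.k
    reads: list[QueryRead] = []
    truths: list[ReadTruth] = []
    sequences = db.sequences()
    for j in range(n_reads):
        origin = sequences[j % len(sequences)]
        bases = list(origin)
        sub_positions: list[int] = []
        if mode == "one_substitution":
            lo = k if non_prefix_only else 0
            sub_positions = [int(rng.integers(lo, len(bases)))]
        elif mode == "random":
            lo = k if non_prefix_only else 0
            sub_positions = [
                i for i in range(lo, len(bases)) if rng.random() < error_rate
            ]
        elif mode != "exact":
            raise FixtureError(f"unknown read mode {mode!r}")
        for pos in sub_positions:
            alternatives = [b for b in "ACGT" if b != bases[pos]]
            bases[pos] = alternatives[int(rng.integers(0, 3))]
        count = int(rng.integers(count_range[0], count_range[1] + 1))
        read = QueryRead(id=f"read{j + 1}", sequence="".join(bases), count=count)
        reads.append(read)
        truths.append(
            ReadTruth(
                read_id=read.id,
                sequence=read.sequence,
                origin_sequence=origin,
                n_substitutions=len(sub_positions),
                substitution_positions=sub_positions,
            )
        )
    for j in range(n_decoys):
        for _ in range(10_000):
            cand = db.site.site + _random_bases(rng, db.L - k).tobytes().decode()
            dists = (
                _capped_distance(cand, target, k) for target in sequences
            )
            if all(d is None or d > decoy_budget for d in dists):
                break
        else:
            raise FixtureError("could not generate a decoy far from all database tags")
        read = QueryRead(id=f"decoy{j + 1}", sequence=cand, count=1)
        reads.append(read)
        truths.append(ReadTruth(read_id=read.id, sequence=cand, origin_sequence=None))
    if out_path is not None:
        write_fastq(reads, out_path)
    return reads, truths
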