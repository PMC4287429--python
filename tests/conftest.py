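"""Shared fixtures: a brute-force search oracle and small database builders.

The brute-force oracle computes, for every stored tag, the Hamming distance
to the query over the query's length, rejecting any tag with more than one
mismatch inside the site prefix and any tag beyond the total budget.  It is
a direct transcription of the matching rule, vectorised with numpy, and
shares no code with the trie.
"""

from __future__ import annotations

import numpy as np
import pytest

from tagtrie.tag_db import TagDatabase, TagEntry
from tagtrie.tag_extraction import SiteSpec


def brute_force_hits(
    db_sequences: list[str], query: str, m: int, k: int
) -> list[tuple[int, int]]:
    """(index, mismatches) for every stored tag within budget.

    Matching is over the query's length (short queries match stored-tag
    prefixes).  Non-ACGT query characters mismatch everything.
    """
    if not db_sequences:
        return []
    q = len(query)
    arr = np.frombuffer("".join(s[:q] for s in db_sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(len(db_sequences), q)
    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    mism = arr != qarr
    total = mism.sum(axis=1)
    prefix = mism[:, : min(k, q)].sum(axis=1)
    keep = (total <= m) & (prefix <= 1)
    return [(int(i), int(total[i])) for i in np.flatnonzero(keep)]


def db_from_sequences(
    sequences: list[str], site: str = "CATG", source: str = "db1"
) -> TagDatabase:
    """A TagDatabase over explicit tag sequences with trivial provenance."""
    seqs = sorted(set(sequences))
    L = len(seqs[0])
    entries = [
        TagEntry(sequence=s, provenance={source: {f"id_{s}": [(0, "+")]}})
        for s in seqs
    ]
    return TagDatabase(site=SiteSpec(site), L=L, source_labels=[source], entries=entries)


def random_tags(
    rng: np.random.Generator, n: int, L: int, site: str
) -> list[str]:
    """n distinct random tag sequences sharing the site prefix."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out: set[str] = set()
    while len(out) < n:
        suffix = bases[rng.integers(0, 4, size=L - len(site))].tobytes().decode()
        out.add(site + suffix)
    return sorted(out)


@pytest.fixture
def brute_force():
    return brute_force_hits


@pytest.fixture
def make_db():
    return db_from_sequences
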