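"""Prefix tree over the tag database with budgeted-mismatch search.

All tags share the restriction-site prefix and many share longer prefixes,
so a trie stores them compactly and answers exact lookups in time linear in
the query length.  Mismatch search is a depth-first recursion that tracks
two counters along the path: total mismatches (bounded by the user budget
``m``) and mismatches inside the first k bases (bounded by 1, always).

The asymmetric prefix rule reflects the biology: every experimental tag was
physically cut at a real restriction site, so its first k bases are the
canonical site; a stored tag whose prefix differs can only be a reference
polymorphism, and one substitution is the most the method credits.  Two
prefix mismatches are never accepted, however large ``m`` is.  A prefix
mismatch still counts against ``m`` — the cap constrains the budget, it
does not extend it.

Queries shorter than the stored tag length are supported: they match every
stored tag whose prefix agrees within budget, which is what makes a
database built for long tags usable with shorter sequencing reads.  ``N``
in a query is always a mismatch, never a wildcard.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import QueryTooLongError
from .tag_db import TagDatabase, TagEntry

BASES = "ACGT"


class TrieNode:
    """One trie node: children keyed by base; a terminal entry at depth L."""

    __slots__ = ("children", "entry")

    def __init__(self) -> None:
        self.children: dict[str, TrieNode] = {}
        self.entry: TagEntry | None = None


@dataclass(frozen=True)
class SearchBudget:
    """Mismatch budget: at most ``max_mismatch`` overall, at most one below
    ``prefix_len``.  The prefix cap is structural and not user-tunable."""

    max_mismatch: int
    prefix_len: int
    max_prefix_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("mismatch budget must be >= 0")
        if self.prefix_len < 1:
            raise ValueError("prefix length must be >= 1")


def build_trie(db: TagDatabase) -> TrieNode:
    """Build the prefix tree over all database entries.

    Traversing children in A,C,G,T order and collecting terminals
    reproduces the sorted entry list exactly.
    """
    root = TrieNode()
    for entry in db.entries:
        node = root
        for base in entry.sequence:
            child = node.children.get(base)
            if child is None:
                child = TrieNode()
                node.children[base] = child
            node = child
        node.entry = entry
    return root


def iter_entries(node: TrieNode) -> list[TagEntry]:
    """All terminal entries under ``node``, in A<C<G<T (lexicographic) order."""
    out: list[TagEntry] = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.entry is not None:
            out.append(cur.entry)
        for base in reversed(BASES):
            child = cur.children.get(base)
            if child is not None:
                stack.append(child)
    return out


def _check_length(query: str, L: int) -> None:
    if len(query) > L:
        raise QueryTooLongError(
            f"query of length {len(query)} exceeds the database tag length {L}; "
            f"trim the read or rebuild the database with a longer tag length"
        )


def search_exact(root: TrieNode, query: str, L: int) -> list[TagEntry]:
    """Exact lookup; a short query returns every entry it prefixes.

    ``N`` never matches any branch, so a query containing ``N`` has no
    exact hits.
    """
    _check_length(query, L)
    node = root
    for base in query:
        node = node.children.get(base)  # type: ignore[assignment]
        if node is None:
            return []
    if len(query) == L:
        return [node.entry] if node.entry is not None else []
    return iter_entries(node)


def search_mismatch(
    root: TrieNode, query: str, budget: SearchBudget, L: int
) -> list[tuple[TagEntry, int]]:
    """All entries within the budget, each with its minimal mismatch count.

    Recursion explores children in fixed A,C,G,T order and prunes as soon
    as either counter would overflow; results are deduplicated per entry
    (keeping the minimal count) and returned sorted by entry sequence for
    determinism.  With ``max_mismatch=0`` this reduces exactly to
    :func:`search_exact`.
    """
    _check_length(query, L)
    m = budget.max_mismatch
    k = budget.prefix_len
    prefix_cap = budget.max_prefix_mismatch
    qlen = len(query)
    best: dict[int, tuple[TagEntry, int]] = {}

    def collect(node: TrieNode, mm: int) -> None:
        for entry in iter_entries(node):
            key = id(entry)
            prev = best.get(key)
            if prev is None or mm < prev[1]:
                best[key] = (entry, mm)

    def walk(node: TrieNode, i: int, mm: int, pmm: int) -> None:
        if i == qlen:
            collect(node, mm)
            return
        q = query[i]
        for base in BASES:
            child = node.children.get(base)
            if child is None:
                continue
            if base == q:
                walk(child, i + 1, mm, pmm)
            else:
                nmm = mm + 1
                if nmm > m:
                    continue
                npmm = pmm + (1 if i < k else 0)
                if npmm > prefix_cap:
                    continue
                walk(child, i + 1, nmm, npmm)

    walk(root, 0, 0, 0)
    return sorted(best.values(), key=lambda hit: hit[0].sequence)
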