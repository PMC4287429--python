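# Methods

## The mapping problem

A DGE library consists of single-end reads that all begin at the
recognition site of the restriction enzyme used in library construction
(k = 4 for the common NlaIII site CATG) and extend a fixed length L
downstream (L = 16–76 bp depending on platform and trimming). Rather than
aligning reads against whole reference sequences, `tagtrie` enumerates the
complete, finite set of tags each reference could produce and reduces
mapping to approximate dictionary lookup. This both shrinks the search
space and guarantees that every reported hit is a fragment the enzyme
could actually have produced.

## Tag extraction

Each reference sequence is scanned once, on the forward strand, for every
k-window within Hamming distance 1 of the site; any non-ACGT character
counts as a mismatch. Overlapping occurrences are all kept. At an
occurrence p (0-based; all intervals half-open):

- forward tag `seq[p : p+L]`, emitted iff `p + L <= len(seq)`;
- reverse tag `revcomp(seq[p-(L-k) : p+k])`, emitted iff `p >= L-k`.

For a reverse-palindromic site each occurrence is simultaneously a
reverse-strand site, so one scan feeds both rules. For a non-palindromic
site a second scan for `revcomp(site)` (same 1-mismatch tolerance)
supplies the reverse tags; the forward occurrences are not reused, since
the two motifs then differ. A tag window containing a non-ACGT character
is dropped entirely: the search alphabet is {A,C,G,T}, and storing N would
require a wildcard semantics the matching rule does not define.

The suppression of forward tags within L of a sequence end is deliberate:
a real read from such a site would run into poly-A/adapter sequence.
Recovering those sites requires trimmed reads and a database built with a
smaller L; the tag length is a command-line parameter precisely so users
can build several databases.

Stored tags are kept exactly as read off the reference. A reference whose
site carries a polymorphism contributes a tag with a variant prefix; an
experimental read (which always carries the canonical site) still finds it
through the one-mismatch search. This is the mechanism by which reference
SNPs inside the site are rescued rather than lost.

## The merged database (db_tags)

Tags from up to three sources are merged by sequence. "Alphanumeric"
ordering is plain lexicographic byte order on uppercase sequences —
deterministic and sufficient for merge-by-adjacency. Each distinct
sequence keeps provenance as `source -> sequence id -> [(position,
strand), ...]`; merging is order-independent and conserves the total
occurrence count. The on-disk format is versioned, headered, tab-delimited
text (optionally gzipped): one line per occurrence, sorted by tag. A
cached file is reused only when its header matches the requested site and
tag length; anything else is rebuilt with a logged notice. Text was chosen
over a serialized trie because the trie builds in seconds at desk scale
and a flat file stays inspectable and diffable.

## Trie search and the prefix cap

The trie holds one node per distinct prefix; terminals sit at depth L.
Exact search walks the query; a query of length q < L returns every entry
below the reached node, which is how a database built for long tags serves
shorter reads. Mismatch search is a depth-first recursion over children in
fixed A,C,G,T order carrying two counters: total mismatches (<= m, the
user budget) and mismatches at query positions < k (<= 1, always). Both
prune immediately on overflow. A prefix mismatch counts toward m — the cap
constrains the budget rather than granting a free extra mismatch; this is
the conservative reading of the rule and the one under which m=0 reduces
exactly to exact search. `N` in a query mismatches every branch (never a
wildcard). Results are deduplicated per entry with the minimal mismatch
count and returned sorted by tag sequence; sorting, rather than DFS
first-visit order, is the documented determinism contract because minimal-
count deduplication makes visit order ambiguous for short queries.

The default budget is m = 1. Indels are out of scope: the method is
strictly substitution (Hamming) matching, as the fixed-position anchoring
of DGE tags warrants.

## Annotation semantics

Per read and per source, hits are bucketed into *exact* (0 mismatches) and
*degenerate* (>= 1). Counts are **distinct source sequence ids**, not tag
or occurrence counts: the question the columns answer is "how many
reference entries could have produced this read". Within a source, an id
reachable both exactly and degenerately (via different tags) is reported
only as exact, so no transcript is double-counted. Long id lists are
truncated for display (default 25 per cell, `...` marker, configurable)
but the count columns are always exact. Empty cells render as `-` with
count 0, and every read gets a row — a transcript miss with a genomic hit
is the signature of a potential novel transcript, so absence is data. No
priority scheme (e.g. RefSeq over UniGene) is applied: the table exposes
everything and leaves weighting to the analyst. Reads longer than L are
flagged `overlength` and left unmapped (trimming is upstream's job); reads
shorter than the site are flagged `short`.

The summary statistics (percent exact, degenerate-only, unmapped) are
weighted by collapsed read counts, since counts are the quantity DGE
measures.

## Collapsing convention

Identical reads are collapsed to one entry whose name carries the total as
a terminal `-<integer>` suffix (`tag1-37` = 37 reads); a name without the
suffix means one read. The suffix syntax is an artifact choice — the
convention that the name field holds the count does not fix one — selected
because it is unambiguous and round-trips through FASTQ. Input may be
pre-collapsed or raw; collapsing is on by default and can be disabled.

## Synthetic data generator

Fixtures plant non-overlapping sites (spacing >= 2L-k, so tag footprints
are disjoint) into random background, then iteratively redraw any
background window that strays within Hamming 1 of the site (or of its
reverse complement, for non-palindromic sites), never touching planted
bases. The planted truth table is therefore *exhaustive*: scanning the
FASTA must reproduce it exactly. Options plant one-mismatch variant sites
(emulating reference polymorphisms) and boundary sites closer than L to an
end (exercising the strand-suppression rules). Read generation samples
tags cyclically (so n_reads >= database size covers every tag) with three
error models: none, exactly one substitution (optionally restricted to
non-prefix positions), or independent per-base errors; decoy reads are
site-prefixed random sequences verified at generation time, by brute
force, to lie more than the search budget away from every stored tag.
Qualities are constant `I` because the method ignores them. Generation is
a pure function of the seed.

What the generator does **not** emulate: expression-level skew, isoform
structure, quality-correlated errors, adapter/poly-A contamination, or
genome-scale repeat structure. Passing tests therefore demonstrate
correctness of the matching rules and pipeline plumbing, not robustness to
real-library artifacts — trimming and quality control remain upstream
responsibilities, and genomic repeats will simply manifest as large
(truncated-for-display) id lists.

## Numerical and scale choices

The pipeline itself contains no randomness; identical configurations
produce byte-identical outputs. Ties in output ordering are resolved
lexicographically everywhere (entries, id lists); collapsed reads are
ordered by descending count then sequence. Degenerate inputs are handled
explicitly: empty FASTA/FASTQ give empty (header-only) outputs, empty
databases give a childless trie root, and infeasible fixture
specifications raise rather than silently shrink.

Verification runs use desk-scale problem sizes — databases of 500–5,000
tags and query sets of 200–1,000 for the brute-force-oracle comparison,
10–100 fixture replicates elsewhere — chosen to exercise every code path
(all budgets, short queries, boundary sites, polymorphic sites) while the
whole suite completes in about a minute. The trie and the brute-force
comparator are independent implementations of the same matching rule;
their agreement on randomized instances is the package's core correctness
evidence.

## Known limitations

- Tag databases are held in memory; the target is desk-scale references
  (transcriptomes, small genomes), not a 76-bp index of a whole vertebrate
  genome.
- Substitutions only; an indel in a tag shifts all downstream bases and
  will generally push the read over budget.
- One tag length per database; mixed-length studies need one database per
  length.
- The maximum useful m is bounded in practice by specificity, not by the
  implementation (any m >= 0 is accepted).
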