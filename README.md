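# tagtrie

Restriction-site-anchored tag extraction and trie-based tag-to-gene mapping
for Digital Gene Expression (DGE) sequencing.

DGE (the modern descendant of SAGE) quantifies transcripts by sequencing
exactly one read per RNA molecule: the fixed-length fragment that starts at
the 3'-most restriction site (e.g. NlaIII's `CATG`) of each transcript.
Because each molecule is hit once, raw tag counts *are* transcript
abundances — no length normalisation is needed — which makes the whole
analysis hinge on one step: assigning each sequenced tag to the reference
entries that could have produced it. `tagtrie` does that step, for up to
three reference databases at once (typically a conservative transcript set
such as RefSeq, a liberal one such as UniGene, and genomic DNA), and emits a
single parsed, tab-delimited annotation so no alignment post-processing is
needed.

## Method

1. **Tag database (db_tags).** Each reference FASTA is scanned on one
   strand for every occurrence of the k-bp site allowing one mismatch
   (rescuing sites mutated in the reference by polymorphisms). Each
   occurrence yields up to two L-bp tags: the bases from the site downstream
   (`+`), and the reverse complement of the site plus its upstream bases
   (`-`); for a reverse-palindromic site one scan serves both strands. Sites
   closer than L to the 3' end yield no forward tag. Tags are sorted
   lexicographically and merged across sources into one store with full
   provenance (source, sequence id, position, strand).

2. **Trie search.** The tags are loaded into a prefix tree: exact lookup is
   O(L), and mismatch search is a pruned recursion tracking two counters —
   total mismatches, bounded by the user budget *m*, and mismatches inside
   the k-bp site prefix, bounded by **1 regardless of m**. The asymmetry is
   biological: an experimental tag always carries the canonical site, so a
   prefix mismatch can only be a reference polymorphism, and one is the most
   the method credits. Reads shorter than L match on their own length, so a
   long-tag database still serves shorter sequencing runs.

3. **Annotation.** Each unique read (identical reads are collapsed, with
   the count kept in the read name as a `-<count>` suffix) gets one output
   row: per source, the ids hit exactly and the ids hit with >= 1 mismatch,
   each with an exact count of distinct entries matched. A read with no
   transcript hit but a genomic hit marks a potential novel transcript.

## Worked example

`python examples/build_and_search.py` simulates three small reference
sources with planted CATG sites, builds a 16-bp tag database, and maps 25
collapsed reads (20 error-free, 5 with one substitution) with `m=1`:

```
merged tag database: 24 distinct 16-bp tags (24 occurrences) from 3 sources

#read_id  count  sequence          refseq_exact_ids  refseq_exact_n  refseq_mm_ids  refseq_mm_n  ...  flag
read1     1      CATGACGGCCAGTCTG  refseq_seq1       1               -              0            ...  -
read2     1      CATGACGGGATAGCCG  -                 0               -              0            ...  -

25 reads: 80.0% exact, 20.0% degenerate-only, 0.0% unmapped
```

`read1` hit exactly one RefSeq entry with zero mismatches; the `*_exact_n`
and `*_mm_n` columns always carry the true number of distinct entries
matched, even when long id lists are truncated for display. The summary
line is count-weighted: the 5 error-carrying reads land in the degenerate
bucket, giving the 80/20/0 split.

`python examples/prefix_cap_demo.py` shows the asymmetric mismatch rule on
a toy database, and `examples/cli_walkthrough.sh` runs the same pipeline
through the command line:

```
tagtrie build  --site CATG --tag-length 16 --db refseq=refseq.fa \
               --db unigene=unigene.fa --db genome=genome.fa --db-tags db_tags.tsv
tagtrie search --site CATG --tag-length 16 --mismatches 1 \
               --fastq reads.fastq --db-tags db_tags.tsv --out annotation.tsv
```

`tagtrie run` does both in one invocation and reuses an existing db_tags
file when its header matches the requested site and tag length.

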