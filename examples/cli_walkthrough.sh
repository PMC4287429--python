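#!/usr/bin/env bash
# The shell workflow: simulate a dataset, build db_tags, then map reads.
# `tagtrie run` does build+search in one go and reuses a matching cache.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

tagtrie simulate --site CATG --tag-length 16 --out-dir "$workdir/sim" --seed 7

tagtrie build --site CATG --tag-length 16 \
    --db "db1=$workdir/sim/db1.fasta" \
    --db "db2=$workdir/sim/db2.fasta" \
    --db "db3=$workdir/sim/db3.fasta" \
    --db-tags "$workdir/db_tags.tsv"

tagtrie search --site CATG --tag-length 16 --mismatches 1 \
    --fastq "$workdir/sim/reads.fastq" \
    --db-tags "$workdir/db_tags.tsv" \
    --out "$workdir/annotation.tsv"

head -3 "$workdir/annotation.tsv"
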