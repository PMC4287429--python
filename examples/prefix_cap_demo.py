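"""The asymmetric mismatch rule, on a four-tag toy database.

Every experimental DGE tag physically begins at the restriction site, so
mismatches inside the 4-bp site prefix can only be reference polymorphisms:
one is tolerated (it rescues reference SNPs), two are never accepted, no
matter how large the overall budget.  Mismatches after the prefix follow
the user budget normally.
"""

from tagtrie import SearchBudget, SiteSpec, build_trie, search_mismatch
from tagtrie.tag_db import TagDatabase, TagEntry

tags = ["CATGAAAA", "CATGAATT", "CATTAAAA", "CTTGAAAA"]
db = TagDatabase(
    site=SiteSpec("CATG"), L=8, source_labels=["demo"],
    entries=[TagEntry(s, {"demo": {f"tag_{s}": [(0, "+")]}}) for s in sorted(tags)],
)
root = build_trie(db)

for query, m in [("CATGAAAA", 0), ("CATGAAAT", 1), ("CTTGAAAA", 1),
                 ("CTAGAAAA", 2), ("CATGATTT", 3)]:
    budget = SearchBudget(max_mismatch=m, prefix_len=4)
    hits = search_mismatch(root, query, budget, db.L)
    shown = ", ".join(f"{e.sequence} ({mm} mm)" for e, mm in hits) or "no hits"
    print(f"query {query}  m={m}:  {shown}")

print()
print("CTAGAAAA never reaches CATGAAAA even at m=2: both of its mismatches to")
print("that tag fall inside the site prefix, which never tolerates more than one.")
print("It still finds CTTGAAAA (one prefix mismatch, within the cap).")
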