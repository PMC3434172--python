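"""Compute the rSPR distance and hybridization number of a small tree pair.

The two 3-taxon trees below disagree on the placement of b and c: one rSPR
move turns one into the other (d = 1), and one reticulation suffices to
display both (h = 1), with three distinct MAAF classes.
"""

from fasthn import augment_dummy, enumerate_maafs, parse_newick, rspr_distance

t1 = augment_dummy(parse_newick("((a,b),c);"))
t2 = augment_dummy(parse_newick("((a,c),b);"))

d = rspr_distance(t1, t2)
result = enumerate_maafs(t1, t2)

print(f"rSPR distance d = {d}")
print(f"hybridization number h = {result.h}")
print(f"number of MAAFs = {len(result.maafs)}")
for rec in result.maafs:
    print("  MAAF:", " | ".join(",".join(comp) for comp in rec.canonical_key))
# d is the size of a maximum agreement forest; h >= d because MAAFs must
# additionally have an acyclic cross-tree ancestry (decision) graph.
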