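"""Enumerate a representative set of minimum hybridization networks.

Generates a benchmark pair (random 10-leaf tree plus 3 random rSPR moves),
enumerates all MAAFs, and prints one minimum hybridization network per
MAAF in extended Newick.  Each network has exactly h reticulations and
displays both input trees; distinct MAAFs give networks with distinct
component partitions, so the list is a representative set.
"""

from fasthn import (
    augment_dummy,
    displays,
    enumerate_maafs,
    generate_pair,
    network_from_maaf,
    write_enewick,
    write_newick,
)
from fasthn.simulate import SimulationConfig

a, b = generate_pair(SimulationConfig(n_leaves=10, r_moves=3, seed=11))
print("T1 =", write_newick(a))
print("T2 =", write_newick(b))

t1, t2 = augment_dummy(a), augment_dummy(b)
result = enumerate_maafs(t1, t2)
print(f"hybridization number h = {result.h}; {len(result.maafs)} MAAF(s)")

for i, rec in enumerate(result.maafs, start=1):
    net = network_from_maaf(rec, t1, t2)
    assert displays(net, t1) and displays(net, t2)
    print(f"network {i}: {write_enewick(net)}")
# every '#Hi' tag marks one reticulation (a hybridization event); the tag
# appears twice because the reticulate lineage has two parents.
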