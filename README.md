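# fasthn

Hybridization numbers, maximum acyclic agreement forests, and minimum
hybridization networks for pairs of rooted binary phylogenetic trees.

## The problem

Two genes sampled from the same set of species can support two different,
well-resolved rooted trees.  When the disagreement is caused by reticulate
evolution — hybridization, recombination, lateral gene transfer — the joint
history is not a tree but a rooted network whose in-degree-2 nodes
(*reticulations*) mark the reticulate events.  Given two rooted binary trees
T₁ and T₂ on the same taxon set X, this package answers three questions:

1. **HN** — what is the *hybridization number* h(T₁,T₂), the minimum number
   of reticulations of any network displaying both trees?
2. **MAAF** — construct one minimum hybridization network.
3. **MAAFs** — enumerate a *representative set* of minimum networks: one
   network per class, where two networks are equivalent when deleting their
   reticulation edges leaves the same partition of X.

The combinatorial core is the *agreement forest*.  A forest F is an
agreement forest (AF) of T₁ and T₂ if both trees can be turned into F by
*detaching* operations (cut a pendant subtree, contract the vacated node);
its size is its number of components minus one.  The minimum AF size is the
rSPR distance d(T₁,T₂).  Orienting the components of F by cross-tree
ancestry gives its *decision graph*; when that digraph is acyclic, F is an
acyclic agreement forest (AAF).  The minimum AAF size equals h(T₁,T₂), and
the minimum-size AAFs (MAAFs) are exactly the representative network
classes — so the whole task reduces to enumerating all MAAFs and building
one network from each.

Both problems are NP-hard; the solver is a depth-bounded exhaustive search
with iterative deepening over the budget k, made practical by

* **subtree and cluster reductions** (preprocessing): common pendant
  subtrees collapse to single leaves, and common clusters split the
  instance into independent subproblems whose h values add and whose MAAF
  sets recombine as a Cartesian product;
* **Heuristic 1** (rSPR-distance pruning): before each branching, a fast
  decision procedure checks whether the remaining budget can still reach an
  agreement forest, and prunes the branch if not;
* **Heuristic 2** (far-apart sibling pairs): the sibling pair driving the
  branching is chosen as far apart as possible in the other forest, which
  avoids or fattens the expensive path-cutting branch.

All eight on/off combinations of (cluster reductions, Heuristic 1,
Heuristic 2) return identical results; the switches trade running time only.

## Worked example

Input files (Newick, one rooted binary tree each, labels over
`0-9 a-z A-Z _ .`):

```sh
$ printf '((a,b),c);' > T1.nwk
$ printf '((a,c),b);' > T2.nwk
$ fasthn T1.nwk T2.nwk HN
1
$ fasthn T1.nwk T2.nwk MAAFs
h: 1
MAAF 1:
a
b,c
network 1: ((a#H1,b),(#H1,c));
MAAF 2:
a,b
c
network 2: (((a,c#H1),b),#H1);
MAAF 3:
a,c
b
network 3: (((a,b#H1),c),#H1);
```

One reticulation reconciles the two placements of b and c (`h: 1`), and
there are exactly three ways to choose the component that moves: detach
`a`, `b`, or `c`.  Each MAAF is printed as the leaf sets of its component
trees (one component per line, canonical order); its network follows in
extended Newick, where the `#H1` tag names the reticulate lineage and
appears twice because that lineage has two parents.  Every emitted network
has exactly h in-degree-2 reticulations and displays both input trees; the
strings open directly in extended-Newick viewers such as Dendroscope.

The optional fourth argument is a 3-bit string (default `111`) switching
cluster reductions, Heuristic 1 and Heuristic 2; `--json` emits a single
machine-readable document.  `MAF`/`MAFs` print maximum agreement forests
instead (their level is the rSPR distance d).  Benchmark instances come
from the companion generator — a random n-leaf tree followed by r random
rSPR moves, so d ≤ r by construction:

```sh
$ fasthn-simulate T1.nwk T2.nwk -n 20 -r 4 --seed 7
{"n": 20, "r": 4, "seed": 7, "t1": "T1.nwk", "t2": "T2.nwk"}
```

The same functionality is available as a library (`fasthn.rspr_distance`,
`fasthn.enumerate_maafs`, `fasthn.network_from_maaf`, `fasthn.solve`, ...);
the `examples/` directory holds short narrative scripts.

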