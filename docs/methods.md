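# Methods

## Model and definitions

A *rooted binary forest* is a DAG in which every node has in-degree ≤ 1 and
every non-leaf exactly two children; its *size* is its number of component
roots minus one.  Leaves carry *label sets* — disjoint, non-empty sets of
taxon names — so that merging identical subtrees into single leaves (the
in-search subtree reduction) loses no information.  Before any
agreement-forest computation, each input tree is augmented with a new root
whose children are the old root and a reserved *dummy leaf* ρ; ρ anchors
the root components on both sides and is represented out-of-band (a
non-alphabet sentinel), so it can never collide with an input taxon.  All
user-facing output strips ρ.

An *agreement forest* (AF) of T₁ and T₂ is a forest reachable from both
trees by detaching operations; the minimum size d is the rSPR distance.
The *decision graph* G_F of an AF has the component roots as vertices and
an arc r₁→r₂ whenever r₁'s image is a proper ancestor of r₂'s image in
either tree (images: a leaf maps to the leaf with the same label set, an
internal node to the LCA of its leaf descendants).  AFs with acyclic G_F
are *acyclic agreement forests* (AAFs); the minimum AAF size equals the
hybridization number h, and the minimum-size AAFs (MAAFs) are in bijection
with the representative classes of minimum hybridization networks.

## The bounded search

The search state is a forest pair (F₁, F₂) with a budget: a branch dies as
soon as size(F₁) exceeds k + k₀ (k₀ being the size of the starting
forest).  Repeatedly, a sibling-leaf pair (u, v) of F₂ is chosen.  If their
counterparts are siblings in F₁ the two cherries merge (forced, no
branching).  Otherwise: different F₁ components → branch on detaching u or
v; same component → branch on detaching u, detaching v, or detaching every
pendant subtree off the u–v path.  In *decision* mode the classical
shortcut applies when exactly one pendant lies on the path (the move is
forced); the shortcut can lose alternative minimum forests, so
*enumeration* mode folds it into the general case and keeps searching
after each success.  Whenever a detached F₁ subtree is a single leaf, the
same leaf is detached in F₂, which maintains the three search invariants
(size(F₁) ≥ size(F₂); at most one F₂ component has edges; edgeless
components correspond one-to-one).  When F₁ becomes edgeless, its leaf
label sets describe an AF, materialized by detaching, for each set without
ρ, the subtree of T₁ rooted at the LCA of the set.

rSPR distance and hybridization number both use iterative deepening over
k = 0, 1, 2, …, so no minimality proof is ever needed: the first level that
succeeds is minimal by construction.  At each level of the MAAF
enumeration, every streamed AF is tested for acyclicity; cyclic ones enter
*cycle breaking*: a directed cycle of G_F survives any detaching that does
not delete one of its vertices, so it suffices to try deleting each cycle
vertex (one detaching — either child gives the same two components),
except the parent of ρ, which would strand the dummy.  Recursion continues
until acyclic or the budget is spent; visited families are memoized.
Records are deduplicated by their *canonical key* — the sorted family of
sorted taxon sets, ρ stripped — which identifies an AF because component
topologies are induced subtrees, and which matches the network-class
equivalence (partitions of X).

### Heuristics

*Heuristic 1* calls the decision procedure (rSPRDC) on the current (F₁,F₂)
with the remaining budget immediately before every multi-child branching
and prunes on failure.  Because it only removes branches that could never
complete, the emitted AF stream is exactly unchanged.  *Heuristic 2*
replaces the default pair choice (first cherry in canonical traversal
order) by the pair whose F₁ counterparts are farthest apart — separation
is the undirected path edge count, with different components counting as
+∞ (those pairs skip the path-cutting branch entirely); ties break
lexicographically.  Changing the selection changes which *optional*
non-maximal AFs appear in the stream, but all required families and every
derived result (d, h, MAF set, MAAF set) are invariant; the test suite
asserts exactly this.

## Reductions

Preprocessing interleaves two MAAF-preserving reductions until neither
applies.  The *subtree reduction* merges common cherries bottom-up, which
collapses every maximal common pendant subtree into one merged-label leaf.
The *cluster reduction* finds a smallest common cluster (non-root internal
nodes of both trees spanning the same taxa), splits it off as an
independent subproblem, and replaces it by a single merged leaf; discovery
is smallest-first, so nested clusters split innermost-first.  Each
subproblem is dummy-augmented independently, so the ρ-handling (including
the cycle-breaking exclusion) is uniform.  Recombination: h values add;
for each choice of one MAAF per subproblem, the inner MAAF's ρ-component
(ρ stripped) replaces the cluster leaf inside the outer component holding
it and the inner non-root components join verbatim, giving the Cartesian
product of the per-subproblem MAAF sets.  Combined families are
re-materialized on the original trees, so networks are always built in
original coordinates.  Reductions run only in preprocessing — inside the
search the merge rule already performs subtree reduction, and cluster
discovery is quadratic, too expensive per search node.

The `MAF`/`MAFs` modes bypass the cluster reduction: hybridization numbers
are additive across common clusters but the rSPR distance in general is
not, so maximum agreement forests are always computed on the full pair.

## Networks

The network for an AAF F of size h starts as a copy of T₁, which embeds
every component at its T₁ position.  A replay pass detaches the components
from a working copy of T₂ in reverse topological order of G_F, recording
for each component the node above which it hung at the moment of its cut.
Re-attaching in forward order splices one new junction node per component
into the growing network immediately above the recorded position (on the
T₂-side in-edge when that position is itself a reticulation) and wires the
junction to the component's root.  Each non-root component root thus has
one parent from its T₁ position and one from its T₂ position: exactly h
reticulations, each of in-degree 2.  Keeping the T₁-side (resp. T₂-side)
in-arc of every reticulation and contracting yields T₁ (resp. T₂); the
chain splice order reproduces T₂'s attachment order above shared anchors,
which the display-oracle tests confirm on every generated MAAF.  The dummy
leaf and the nodes it leaves unifurcate are stripped before output.  One
network is emitted per MAAF; enumerating all minimum networks inside one
class is out of scope.

The *display* check is an oracle, exponential in h by design: it tries all
2^h switchings (one in-arc kept per reticulation), prunes unreachable and
taxon-free nodes, contracts, and compares canonical shapes.  *Forest
extraction* deletes all reticulation in-edges, prunes and contracts; on a
constructed network it returns exactly the source MAAF's partition.
Extended Newick output assigns `#Hi` tags in deterministic traversal
order; the dialect is bare hybrid tags (no lengths, no γ annotations),
and a reparse yields an isomorphic network (checked with a VF2 matcher on
the labelled DAGs).

## Synthetic data

The generator reproduces the standard benchmark protocol: a random rooted
binary tree on n leaves (sequential attachment — each new leaf subdivides
a position chosen uniformly among all edges plus the root position; the
exact distribution of the original benchmark generator is unspecified, so
this documented, seeded choice stands in), followed by r random rSPR moves
(prune a uniform non-root edge, regraft onto a uniform legal edge;
re-attachment to the vacated edge is excluded as a no-op, and impossible
moves are skipped with a log notice).  By construction d ≤ r; h may be
below, equal to, or — rarely at these sizes — above r.  The generator does
not emulate features of real gene trees (taxon sampling biases, large
common clusters, rate heterogeneity), so passing tests certify the
combinatorial algorithms, not inference quality on empirical data; real
pairs enter through the Newick front end.

The exhaustive oracles cut every k-subset of T₁'s edges (k ascending),
certify candidates against T₂ directly (embedding shapes plus disjointness
of spanning subtrees), and filter by an independent acyclicity test; they
share no code with the search modules and refuse instances above 12
leaves.

## Problem sizes and numerical choices

The default verification sizes are chosen for exhaustive confirmability:
oracle sweeps use n = 4..8 with r = 0..3 (10 seeds each, 200 pairs);
heuristic-invariance checks use 20-leaf pairs with r = 3..5 across all 8
switch settings; network contracts are checked whenever h ≤ 5 (the display
oracle grows as 2^h).  Everything is exact integer/set computation — no
floating-point tolerances exist anywhere.  Determinism is fixed
throughout: children order by smallest descendant label, components by
canonical key, branch order is (detach u, detach v, path-detach), cycle
vertices are tried in canonical component order, and all randomness flows
from explicit seeds.

## Known limitations

* Worst-case running time is exponential in h (the problems are NP-hard);
  the implementation targets desk-scale instances (tens of taxa, h up to
  ~10 in reasonable time) rather than the largest published benchmarks.
* Chain reduction is deliberately not implemented: it produces weighted
  trees, which the bounded search does not support.
* Input trees must be binary and share their taxon set; multifurcations
  are rejected rather than resolved.
* The display check and the MAAF-to-network construction assume h small
  enough for 2^h verification; construction itself is polynomial per MAAF.
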