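"""Rooted binary forests with label-set leaves.

This is the universal substrate of the package: input phylogenetic trees,
intermediate search forests and agreement forests are all instances of
:class:`Forest`.  Every leaf carries a non-empty *label set* (a frozenset of
taxon names, possibly including the out-of-band dummy sentinel); label sets
are pairwise disjoint across the whole forest.  Internal nodes always have
exactly two children.

Node identifiers are small integers that stay stable under detaching and
contraction, so a node of a derived forest can be traced back to the tree it
was carved out of.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

__all__ = [
    "DUMMY",
    "Forest",
    "SiblingPair",
    "ForestError",
    "size",
    "detach",
    "merge_sibling_leaves",
    "select_sibling_pair",
    "af_from_labelsets",
    "node_correspondence",
]

#: Sentinel taxon for the dummy leaf attached beside the original root.  The
#: character is outside the legal label alphabet (digits, ASCII letters, "_",
#: "."), so it can never collide with a user taxon.  Debug output renders it
#: as "rho".
DUMMY = "ρ"

INF = float("inf")


class ForestError(ValueError):
    """Violation of a forest-operation precondition."""


@dataclass(frozen=True)
class SiblingPair:
    """A pair of sibling leaves, with their separation in the other forest."""

    u: int
    v: int
    separation: float  # edge count, or inf when in different components


def _sort_key(label_set: frozenset) -> tuple:
    return tuple(sorted(label_set))


class Forest:
    """Mutable rooted binary forest.

    Attributes
    ----------
    parent : dict
        Maps a non-root node to its parent.
    children : dict
        Maps an internal node to its two children (list of length 2).
    labels : dict
        Maps a leaf to its frozenset of taxon names.
    """

    __slots__ = ("parent", "children", "labels", "_next_id")

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}
        self.children: dict[int, list[int]] = {}
        self.labels: dict[int, frozenset] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def new_node(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def add_leaf(self, label_set: Iterable[str], parent: Optional[int] = None) -> int:
        nid = self.new_node()
        self.labels[nid] = frozenset(label_set)
        if parent is not None:
            self.parent[nid] = parent
            self.children.setdefault(parent, []).append(nid)
        return nid

    def add_internal(self, parent: Optional[int] = None) -> int:
        nid = self.new_node()
        self.children[nid] = []
        if parent is not None:
            self.parent[nid] = parent
            self.children.setdefault(parent, []).append(nid)
        return nid

    def copy(self) -> "Forest":
        f = Forest.__new__(Forest)
        f.parent = dict(self.parent)
        f.children = {k: list(v) for k, v in self.children.items()}
        f.labels = dict(self.labels)
        f._next_id = self._next_id
        return f

    # -- basic queries -----------------------------------------------------

    def is_leaf(self, v: int) -> bool:
        return v in self.labels

    def is_root(self, v: int) -> bool:
        return v not in self.parent

    def roots(self) -> list[int]:
        return [v for v in self.nodes() if v not in self.parent]

    def nodes(self) -> Iterator[int]:
        yield from self.children
        yield from self.labels

    def leaves(self) -> list[int]:
        return list(self.labels)

    def num_components(self) -> int:
        return len(self.roots())

    def has_edges(self) -> bool:
        return bool(self.children)

    def root_of(self, v: int) -> int:
        while v in self.parent:
            v = self.parent[v]
        return v

    def sibling(self, v: int) -> int:
        p = self.parent[v]
        a, b = self.children[p]
        return b if a == v else a

    def subtree_nodes(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            x = stack.pop()
            out.append(x)
            stack.extend(self.children.get(x, ()))
        return out

    def subtree_taxa(self, v: int) -> frozenset:
        taxa: set = set()
        for x in self.subtree_nodes(v):
            if x in self.labels:
                taxa |= self.labels[x]
        return frozenset(taxa)

    def taxa(self) -> frozenset:
        out: set = set()
        for s in self.labels.values():
            out |= s
        return frozenset(out)

    def leaf_by_labelset(self, label_set: frozenset) -> int:
        for v, s in self.labels.items():
            if s == label_set:
                return v
        raise KeyError(label_set)

    def depth(self, v: int) -> int:
        d = 0
        while v in self.parent:
            v = self.parent[v]
            d += 1
        return d

    def ancestors(self, v: int) -> list[int]:
        """Strict ancestors of v, nearest first."""
        out = []
        while v in self.parent:
            v = self.parent[v]
            out.append(v)
        return out

    def lca(self, nodes: Iterable[int]) -> int:
        """Lowest common ancestor by naive ancestor walk (desk scale)."""
        it = iter(nodes)
        try:
            acc = next(it)
        except StopIteration:
            raise ForestError("lca of empty node set")
        acc_anc = [acc] + self.ancestors(acc)
        acc_set = set(acc_anc)
        for v in it:
            while v not in acc_set:
                if v not in self.parent:
                    raise ForestError("lca: nodes in different components")
                v = self.parent[v]
            # trim acc chain down to v
            idx = acc_anc.index(v)
            acc_anc = acc_anc[idx:]
            acc_set = set(acc_anc)
        return acc_anc[0]

    def separation(self, u: int, v: int) -> float:
        """Edges on the undirected u-v path; inf across components."""
        if u == v:
            return 0
        anc_u = {u: 0}
        x, d = u, 0
        while x in self.parent:
            x = self.parent[x]
            d += 1
            anc_u[x] = d
        x, d = v, 0
        while True:
            if x in anc_u:
                return d + anc_u[x]
            if x not in self.parent:
                return INF
            x = self.parent[x]
            d += 1

    # -- canonical order ---------------------------------------------------

    def min_taxon(self, v: int) -> str:
        """Smallest taxon name among leaf descendants (canonical sort key)."""
        if v in self.labels:
            return min(self.labels[v])
        a, b = self.children[v]
        return min(self.min_taxon(a), self.min_taxon(b))

    def ordered_children(self, v: int) -> list[int]:
        return sorted(self.children[v], key=self.min_taxon)

    def ordered_roots(self) -> list[int]:
        return sorted(self.roots(), key=self.min_taxon)

    def canonical_leaves(self) -> Iterator[int]:
        """Leaves in deterministic traversal order (canonical DFS)."""
        for r in self.ordered_roots():
            stack = [r]
            while stack:
                x = stack.pop()
                if x in self.labels:
                    yield x
                else:
                    stack.extend(reversed(self.ordered_children(x)))

    def labelset_family(self) -> list[frozenset]:
        """Label sets of the component trees, canonically sorted."""
        fam = [self.subtree_taxa(r) for r in self.roots()]
        return sorted(fam, key=_sort_key)

    def canonical_key(self) -> tuple:
        """Dedup key: sorted family of sorted taxon tuples, dummy stripped.

        Valid as an agreement-forest identity because component topologies
        are induced from the input tree by their leaf sets.
        """
        fam = []
        for s in self.labelset_family():
            t = tuple(sorted(s - {DUMMY}))
            if t:
                fam.append(t)
        return tuple(sorted(fam))

    # -- shape -------------------------------------------------------------

    def shape_key(self, v: Optional[int] = None) -> tuple:
        """Canonical recursive shape of a component (topology + label sets)."""
        if v is None:
            (v,) = self.roots()
        if v in self.labels:
            return ("leaf", _sort_key(self.labels[v]))
        a, b = self.children[v]
        ka, kb = self.shape_key(a), self.shape_key(b)
        return ("node",) + tuple(sorted((ka, kb)))

    def validate(self) -> None:
        """Assert the forest invariants (used by tests and debug paths)."""
        for v, cs in self.children.items():
            if len(cs) != 2:
                raise AssertionError(f"node {v} has {len(cs)} children")
            for c in cs:
                if self.parent.get(c) != v:
                    raise AssertionError("parent/children maps disagree")
        for v, p in self.parent.items():
            if v not in self.children and v not in self.labels:
                raise AssertionError("dangling node")
            if p not in self.children:
                raise AssertionError("parent is not internal")
        seen: set = set()
        for s in self.labels.values():
            if not s:
                raise AssertionError("empty label set")
            if seen & s:
                raise AssertionError("label sets not disjoint")
            seen |= s
        # acyclicity: parent walk from every node must terminate
        for v in list(self.nodes()):
            steps = 0
            x = v
            while x in self.parent:
                x = self.parent[x]
                steps += 1
                if steps > len(self.parent) + 1:
                    raise AssertionError("cycle in parent map")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        fam = [",".join(sorted(s)).replace(DUMMY, "rho") for s in self.labelset_family()]
        return f"Forest({' | '.join(fam)})"


# -- free-standing operations (the spec's primitive surface) ----------------


def size(forest: Forest) -> int:
    """Size of a forest: number of component roots minus one."""
    n = forest.num_components()
    if n == 0:
        raise ForestError("empty forest")
    return n - 1


def detach(forest: Forest, v: int, in_place: bool = False) -> Forest:
    """Detach the subtree rooted at the non-root node ``v``.

    Deletes the edge to v's parent, then contracts the now-unifurcate
    parent (or deletes it when it was a root).  Size grows by exactly one.
    """
    f = forest if in_place else forest.copy()
    if f.is_root(v):
        raise ForestError("cannot detach a root")
    p = f.parent.pop(v)
    f.children[p].remove(v)
    (other,) = f.children[p]
    # contract p
    del f.children[p]
    if p in f.parent:
        gp = f.parent.pop(p)
        cs = f.children[gp]
        cs[cs.index(p)] = other
        f.parent[other] = gp
    else:
        del f.parent[other]
    return f


def merge_sibling_leaves(forest: Forest, u: int, v: int, in_place: bool = False) -> Forest:
    """Merge two sibling leaves into one leaf carrying the union label set."""
    f = forest if in_place else forest.copy()
    if not (f.is_leaf(u) and f.is_leaf(v)):
        raise ForestError("merge requires sibling leaves")
    if f.parent.get(u) is None or f.parent.get(u) != f.parent.get(v):
        raise ForestError("merge requires sibling leaves")
    p = f.parent[u]
    union = f.labels[u] | f.labels[v]
    del f.labels[u], f.labels[v]
    del f.parent[u], f.parent[v]
    del f.children[p]
    f.labels[p] = union
    return f


def select_sibling_pair(
    f2: Forest,
    f1: Forest,
    use_heuristic2: bool = False,
) -> SiblingPair:
    """Pick the sibling-leaf pair of ``f2`` to branch on.

    With the far-apart rule off, this is the first sibling-leaf pair in
    canonical traversal order.  With it on, the pair whose counterpart
    leaves lie as far apart as possible in ``f1`` is preferred (pairs in
    different components count as infinitely far, so they never need the
    expensive path-cutting branch); ties break lexicographically.
    """
    pairs: list[tuple[int, int]] = []
    seen: set = set()
    for leaf in f2.canonical_leaves():
        if leaf in seen or f2.is_root(leaf):
            continue
        sib = f2.sibling(leaf)
        if f2.is_leaf(sib):
            u, v = sorted((leaf, sib), key=lambda x: min(f2.labels[x]))
            pairs.append((u, v))
            seen.add(leaf)
            seen.add(sib)
    if not pairs:
        raise ForestError("no cherry available")
    if not use_heuristic2:
        u, v = pairs[0]
        u1 = f1.leaf_by_labelset(f2.labels[u])
        v1 = f1.leaf_by_labelset(f2.labels[v])
        return SiblingPair(u, v, f1.separation(u1, v1))
    best = None
    for u, v in pairs:
        u1 = f1.leaf_by_labelset(f2.labels[u])
        v1 = f1.leaf_by_labelset(f2.labels[v])
        sep = f1.separation(u1, v1)
        key = (-sep, min(f2.labels[u]), min(f2.labels[v]))
        if best is None or key < best[0]:
            best = (key, u, v, sep)
    _, u, v, sep = best
    return SiblingPair(u, v, sep)


def node_correspondence(forest: Forest, tree: Forest) -> dict[int, int]:
    """Map each forest node to its counterpart in an original tree.

    Leaves map to the leaf with the same label set; a non-leaf maps to the
    LCA of its leaf descendants.  The map is injective per tree and stays
    valid under detach/contract because node identity is preserved.
    """
    out: dict[int, int] = {}
    for r in forest.roots():
        for x in forest.subtree_nodes(r):
            taxa = forest.subtree_taxa(x)
            nodes = [v for v, s in tree.labels.items() if s <= taxa]
            out[x] = tree.lca(nodes)
    return out


def af_from_labelsets(t1: Forest, family: Iterable[frozenset]) -> Forest:
    """Carve the agreement forest with the given label-set family out of t1.

    For every set of the family not containing the dummy, the subtree of t1
    rooted at the LCA of the set's taxa is detached; the family must describe
    a consistent partition (exactly one set holds the dummy).  The returned
    forest keeps t1's node identifiers, so its non-leaf nodes correspond to
    LCAs in t1 directly.
    """
    fam = [frozenset(s) for s in family]
    with_dummy = [s for s in fam if DUMMY in s]
    if len(with_dummy) != 1:
        raise ForestError("exactly one label set must contain the dummy")
    if frozenset().union(*fam) != t1.taxa():
        raise ForestError("inconsistent label-set family")
    f = t1.copy()
    # leaf -> taxa lookup for LCA computation on merged-label leaves
    pending = [s for s in fam if DUMMY not in s]
    while pending:
        progressed = False
        for s in list(pending):
            nodes = [v for v, ls in f.labels.items() if ls <= s]
            covered = frozenset().union(*(f.labels[v] for v in nodes)) if nodes else frozenset()
            if covered != s:
                raise ForestError("inconsistent label-set family")
            try:
                r = f.lca(nodes)
            except ForestError:
                continue
            if f.subtree_taxa(r) != s:
                continue
            if f.is_root(r):
                # already its own component (e.g. detached earlier as a block)
                pending.remove(s)
                progressed = True
                continue
            detach(f, r, in_place=True)
            pending.remove(s)
            progressed = True
        if not progressed:
            raise ForestError("inconsistent label-set family")
    # final check: resulting family matches
    if sorted(f.labelset_family(), key=_sort_key) != sorted(fam, key=_sort_key):
        raise ForestError("inconsistent label-set family")
    return f
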