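"""Maximum acyclic agreement forest enumeration.

An agreement forest ``F`` of two trees induces a *decision graph* on its
component roots: an arc runs from one root to another when the first is a
proper ancestor of the second in either input tree.  ``F`` is *acyclic*
(an AAF) when this digraph has no directed cycle; the minimum AAF size over
all agreement forests equals the hybridization number of the tree pair,
and the minimum-size AAFs (MAAFs) are exactly the representative classes
of minimum hybridization networks.

The enumeration iterates a budget ``k`` upward.  At each level the
enumeration-mode bounded search streams agreement forests; acyclic ones are
recorded directly, cyclic ones are repaired by *cycle breaking*: a directed
cycle can only be destroyed by deleting one of its vertices (detaching a
child of that component root), so trying every cycle vertex — except the
dummy leaf's parent, which would strand the dummy — explores every AAF
refinement within the remaining budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

import networkx as nx

from .forest import DUMMY, Forest, ForestError, af_from_labelsets, detach, size
from .search import enumerate_agreement_forests

__all__ = [
    "DecisionGraph",
    "AgreementForestRecord",
    "MaafResult",
    "decision_graph",
    "find_cycle",
    "break_cycles",
    "gaf_enumerate",
    "enumerate_maafs",
    "hybridization_number",
]


@dataclass
class DecisionGraph:
    """Cross-tree ancestry digraph on the roots of an agreement forest."""

    graph: nx.DiGraph

    @property
    def acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)


@dataclass(frozen=True)
class AgreementForestRecord:
    """One agreement forest, keyed for duplicate-free collection."""

    forest: Forest = field(compare=False)
    canonical_key: tuple  # sorted family of sorted taxon tuples, dummy stripped
    acyclic: bool
    size: int


@dataclass
class MaafResult:
    """Hybridization number plus the duplicate-free MAAF list."""

    h: int
    maafs: list[AgreementForestRecord]
    stats: dict = field(default_factory=dict)


def _image(tree: Forest, taxa: frozenset) -> int:
    """Node of ``tree`` corresponding to a forest node with this taxon set."""
    nodes = [v for v, s in tree.labels.items() if s <= taxa]
    return tree.lca(nodes)


def decision_graph(forest: Forest, t1: Forest, t2: Forest) -> DecisionGraph:
    """Build the ancestry digraph of an agreement forest's roots."""
    roots = forest.roots()
    images = {}
    for r in roots:
        taxa = forest.subtree_taxa(r)
        images[r] = (_image(t1, taxa), _image(t2, taxa))
    anc1 = {r: set(t1.ancestors(images[r][0])) for r in roots}
    anc2 = {r: set(t2.ancestors(images[r][1])) for r in roots}
    g = nx.DiGraph()
    g.add_nodes_from(roots)
    for r1 in roots:
        for r2 in roots:
            if r1 is r2:
                continue
            if images[r1][0] in anc1[r2] or images[r1][1] in anc2[r2]:
                g.add_edge(r1, r2)
    return DecisionGraph(g)


def find_cycle(g: DecisionGraph) -> Optional[list]:
    """Some directed cycle as a vertex list, or None when acyclic."""
    try:
        edges = nx.find_cycle(g.graph)
    except nx.NetworkXNoCycle:
        return None
    return [u for u, _ in edges]


def _full_key(forest: Forest) -> tuple:
    return tuple(sorted(tuple(sorted(s)) for s in forest.labelset_family()))


def _has_dummy_only_component(forest: Forest) -> bool:
    return any(s == frozenset({DUMMY}) for s in forest.labelset_family())


def _record(forest: Forest, acyclic: bool) -> AgreementForestRecord:
    return AgreementForestRecord(
        forest=forest,
        canonical_key=forest.canonical_key(),
        acyclic=acyclic,
        size=size(forest),
    )


def break_cycles(
    forest: Forest, budget: int, t1: Forest, t2: Forest
) -> list[AgreementForestRecord]:
    """All acyclic agreement forests within ``budget`` further detachings.

    Only cycle vertices need deleting: any other detaching leaves the cycle
    intact.  Deleting a root is one detaching operation (either child —
    the resulting two components are the same), and the dummy leaf's
    parent is never deleted, since the dummy alone cannot form a component
    of a minimum AAF.
    """
    out: dict[tuple, AgreementForestRecord] = {}
    visited: set[tuple] = set()

    def walk(f: Forest, remaining: int) -> None:
        key = _full_key(f)
        if key in visited:
            return
        visited.add(key)
        g = decision_graph(f, t1, t2)
        cycle = find_cycle(g)
        if cycle is None:
            if not _has_dummy_only_component(f):
                rec = _record(f, acyclic=True)
                out.setdefault(rec.canonical_key, rec)
            return
        if remaining <= 0:
            return
        dummy_leaf = f.leaf_by_labelset(frozenset({DUMMY}))
        dummy_parent = f.parent.get(dummy_leaf)
        order = sorted(cycle, key=lambda r: tuple(sorted(f.subtree_taxa(r))))
        for r in order:
            if r == dummy_parent or r not in f.children:
                continue
            child = f.children[r][0]
            walk(detach(f, child), remaining - 1)

    walk(forest, budget)
    return sorted(out.values(), key=lambda r: r.canonical_key)


def gaf_enumerate(
    t1: Forest,
    t2: Forest,
    k: int,
    f1: Optional[Forest] = None,
    h1: bool = False,
    h2: bool = False,
) -> Iterator[AgreementForestRecord]:
    """Stream agreement-forest records reachable within ``k`` detachings.

    Families are deduplicated and materialized as subforests of ``t1``;
    each record carries its acyclicity flag.  The emitted set is invariant
    under the heuristic flags, which only prune or reorder the search.
    """
    seen: set[tuple] = set()
    for family in enumerate_agreement_forests(t1, t2, k, f1=f1, h1=h1, h2=h2):
        key = tuple(sorted(tuple(sorted(s)) for s in family))
        if key in seen:
            continue
        seen.add(key)
        forest = af_from_labelsets(t1, family)
        acyclic = decision_graph(forest, t1, t2).acyclic
        yield _record(forest, acyclic)


def _maafs_at_level(
    t1: Forest, t2: Forest, k: int, h1: bool, h2: bool
) -> Iterator[AgreementForestRecord]:
    """All acyclic records obtainable at budget level ``k`` (with repeats)."""
    for rec in gaf_enumerate(t1, t2, k, h1=h1, h2=h2):
        if rec.acyclic:
            if not _has_dummy_only_component(rec.forest):
                yield rec
        else:
            yield from break_cycles(rec.forest, k - rec.size, t1, t2)


def enumerate_maafs(
    t1: Forest, t2: Forest, h1: bool = True, h2: bool = True
) -> MaafResult:
    """Enumerate all maximum acyclic agreement forests of a tree pair.

    Iterative deepening over the budget: the first level producing at
    least one AAF is the hybridization number; the duplicate-free records
    at that level are exactly the MAAFs.
    """
    if t1.taxa() != t2.taxa():
        raise ForestError("taxa differ")
    for k in itertools.count():
        found: dict[tuple, AgreementForestRecord] = {}
        n_records = 0
        for rec in _maafs_at_level(t1, t2, k, h1, h2):
            n_records += 1
            if rec.size != k:
                raise AssertionError("AAF below the current level")
            found.setdefault(rec.canonical_key, rec)
        if found:
            maafs = [found[key] for key in sorted(found)]
            stats = {"h1": h1, "h2": h2, "aaf_records": n_records}
            return MaafResult(h=k, maafs=maafs, stats=stats)


def enumerate_mafs(
    t1: Forest, t2: Forest, h1: bool = True, h2: bool = True
) -> MaafResult:
    """All maximum agreement forests (no acyclicity constraint).

    The first budget level at which the enumeration-mode search emits any
    agreement forest is the rSPR distance; the deduplicated records at
    that level are the MAFs.  The ``h`` field holds the rSPR distance.
    """
    if t1.taxa() != t2.taxa():
        raise ForestError("taxa differ")
    for k in itertools.count():
        found: dict[tuple, AgreementForestRecord] = {}
        for rec in gaf_enumerate(t1, t2, k, h1=h1, h2=h2):
            if rec.size != k:
                raise AssertionError("agreement forest below the current level")
            found.setdefault(rec.canonical_key, rec)
        if found:
            mafs = [found[key] for key in sorted(found)]
            return MaafResult(h=k, maafs=mafs, stats={"h1": h1, "h2": h2, "maf": True})


def hybridization_number(
    t1: Forest, t2: Forest, h1: bool = True, h2: bool = True
) -> int:
    """Hybridization number, stopping at the first MAAF found."""
    if t1.taxa() != t2.taxa():
        raise ForestError("taxa differ")
    for k in itertools.count():
        for _ in _maafs_at_level(t1, t2, k, h1, h2):
            return k
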