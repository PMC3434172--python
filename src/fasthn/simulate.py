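"""Synthetic tree-pair generation and exhaustive ground-truth oracles.

The generator emulates the standard benchmark protocol for agreement-forest
software: draw a random rooted binary tree on ``n`` labelled leaves, then
apply ``r`` random rSPR operations to obtain the second tree, so the actual
rSPR distance of the pair is at most ``r`` (the hybridization number may be
smaller or larger than ``r``).

The oracles enumerate *all* forests obtainable by cutting small edge
subsets of the first tree and certify each candidate against the second
tree directly.  They share no code with the bounded-search modules, so they
serve as an independent reference on desk-scale instances.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass
from typing import Optional

from .forest import DUMMY, Forest, ForestError, detach, size
from .maaf import AgreementForestRecord, MaafResult

__all__ = [
    "SimulationConfig",
    "random_tree",
    "random_rspr",
    "generate_pair",
    "is_af",
    "oracle_maafs",
    "oracle_rspr_distance",
]

log = logging.getLogger(__name__)

ORACLE_MAX_LEAVES = 12


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings: leaves, rSPR walk length, RNG seed."""

    n_leaves: int
    r_moves: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be at least 2")
        if self.r_moves < 0:
            raise ValueError("r_moves must be non-negative")


def random_tree(cfg: SimulationConfig, rng: Optional[random.Random] = None) -> Forest:
    """Random rooted binary tree on leaves t1..tn.

    Sequential random attachment: each new leaf subdivides a position
    chosen uniformly among all current edges plus the position above the
    root, so every topology is reachable and the draw is reproducible
    under the seed.
    """
    rng = random.Random(cfg.seed) if rng is None else rng
    t = Forest()
    t.add_leaf({"t1"})
    for i in range(2, cfg.n_leaves + 1):
        positions = sorted(t.parent) + ["root"]
        pos = rng.choice(positions)
        if pos == "root":
            (old_root,) = t.roots()
            m = t.add_internal()
            t.parent[old_root] = m
            t.children[m].append(old_root)
        else:
            m = t.add_internal()
            p = t.parent[pos]
            cs = t.children[p]
            cs[cs.index(pos)] = m
            t.parent[m] = p
            t.parent[pos] = m
            t.children[m].append(pos)
        t.add_leaf({f"t{i}"}, m)
    return t


def _rspr_once(t: Forest, rng: random.Random) -> Forest:
    """One random rSPR move; returns the input unchanged when no move is legal."""
    non_roots = sorted(t.parent)
    if not non_roots:
        return t
    c = rng.choice(non_roots)
    f = t.copy()
    p = f.parent[c]
    p_was_root = f.is_root(p)
    sibling = f.sibling(c)
    detach(f, c, in_place=True)  # forest: main component + subtree at c
    pruned = set(f.subtree_nodes(c))
    targets = [x for x in sorted(f.parent) if x not in pruned and f.parent[x] not in pruned]
    if not p_was_root and sibling in targets:
        targets.remove(sibling)  # re-attaching there undoes the prune
    if not targets:
        log.info("rSPR move skipped: no legal re-attachment edge")
        return t
    x = rng.choice(targets)
    m = f.add_internal()
    px = f.parent[x]
    cs = f.children[px]
    cs[cs.index(x)] = m
    f.parent[m] = px
    f.parent[x] = m
    f.children[m] = [x, c]
    f.parent[c] = m
    return f


def random_rspr(
    t: Forest, cfg: SimulationConfig, rng: Optional[random.Random] = None
) -> Forest:
    """Apply ``cfg.r_moves`` random rSPR operations to a copy of ``t``."""
    rng = random.Random(cfg.seed) if rng is None else rng
    out = t
    for _ in range(cfg.r_moves):
        out = _rspr_once(out, rng)
    return out


def generate_pair(cfg: SimulationConfig) -> tuple[Forest, Forest]:
    """A reproducible (T, T') benchmark pair with rSPR distance <= r."""
    rng = random.Random(cfg.seed)
    t = random_tree(cfg, rng)
    return t, random_rspr(t, cfg, rng)


# -- agreement-forest certificate -------------------------------------------


def _restricted_shape(t: Forest, v: int, keep: set) -> Optional[tuple]:
    """Canonical shape of t's subtree at v restricted to the leaves ``keep``."""
    if t.is_leaf(v):
        return ("leaf", tuple(sorted(t.labels[v]))) if v in keep else None
    a, b = t.children[v]
    ka = _restricted_shape(t, a, keep)
    kb = _restricted_shape(t, b, keep)
    if ka is None:
        return kb
    if kb is None:
        return ka
    return ("node",) + tuple(sorted((ka, kb)))


def _steiner_nodes(t: Forest, leaves: list[int]) -> set:
    """Nodes of the minimal connected subtree of t spanning ``leaves``."""
    top = t.lca(leaves)
    nodes: set = {top}
    for v in leaves:
        while v not in nodes:
            nodes.add(v)
            v = t.parent[v]
    return nodes


def is_af(forest: Forest, t: Forest) -> bool:
    """Is ``forest`` obtainable from ``t`` by detaching operations?

    True iff the forest's leaf label sets tile t's leaves, every component
    equals the contracted restriction of t to its leaf set, and the
    spanning subtrees of the components are pairwise node-disjoint in t.
    """
    t_leafsets = sorted(map(tuple, map(sorted, t.labels.values())))
    f_leafsets = sorted(map(tuple, map(sorted, forest.labels.values())))
    if t_leafsets != f_leafsets:
        return False
    by_labels = {s: v for v, s in t.labels.items()}
    used: set = set()
    for r in forest.roots():
        leaves_t = [by_labels[forest.labels[v]] for v in forest.subtree_nodes(r) if forest.is_leaf(v)]
        span = _steiner_nodes(t, leaves_t)
        if span & used:
            return False
        used |= span
        shape = _restricted_shape(t, t.lca(leaves_t), set(leaves_t))
        if shape != forest.shape_key(r):
            return False
    return True


# -- exhaustive oracles ------------------------------------------------------


def _cut_edges(t: Forest, children: tuple) -> Optional[Forest]:
    """Forest from cutting the parent edges of ``children`` simultaneously.

    Returns None for degenerate subsets (e.g. both child edges of a root),
    which are equivalent to cutting fewer edges and covered elsewhere.
    """
    f = t.copy()
    for c in sorted(children, key=t.depth):  # shallow first: survives contraction
        if f.is_root(c):
            return None
        detach(f, c, in_place=True)
    return f


def _oracle_acyclic(forest: Forest, t1: Forest, t2: Forest) -> bool:
    """Independent acyclicity test: ancestry arcs + Kahn-style peeling."""

    def image(t: Forest, taxa: frozenset) -> int:
        nodes = [v for v, s in t.labels.items() if s <= taxa]
        return t.lca(nodes)

    roots = forest.roots()
    imgs = {r: (image(t1, forest.subtree_taxa(r)), image(t2, forest.subtree_taxa(r))) for r in roots}
    arcs = {r: set() for r in roots}
    for r1 in roots:
        for r2 in roots:
            if r1 is r2:
                continue
            if imgs[r1][0] in t1.ancestors(imgs[r2][0]) or imgs[r1][1] in t2.ancestors(imgs[r2][1]):
                arcs[r1].add(r2)
    indeg = {r: 0 for r in roots}
    for r, outs in arcs.items():
        for x in outs:
            indeg[x] += 1
    queue = [r for r in roots if indeg[r] == 0]
    seen = 0
    while queue:
        r = queue.pop()
        seen += 1
        for x in arcs[r]:
            indeg[x] -= 1
            if indeg[x] == 0:
                queue.append(x)
    return seen == len(roots)


def oracle_maafs(t1: Forest, t2: Forest) -> MaafResult:
    """Brute-force MAAF enumeration by exhaustive edge-subset cutting.

    Cuts every k-subset of t1's edges (k ascending), keeps the candidates
    that are agreement forests of the pair, filters by decision-graph
    acyclicity and the no-dummy-alone rule, and returns the first
    non-empty level.  Only safe for small instances.
    """
    if len(t1.labels) > ORACLE_MAX_LEAVES:
        raise ForestError("instance too large for the exhaustive oracle")
    if t1.taxa() != t2.taxa():
        raise ForestError("taxa differ")
    edges = sorted(t1.parent)
    d: Optional[int] = None
    for k in range(len(edges) + 1):
        found: dict[tuple, AgreementForestRecord] = {}
        for combo in itertools.combinations(edges, k):
            f = _cut_edges(t1, combo)
            if f is None or size(f) != k:
                continue
            if not is_af(f, t2):
                continue
            if d is None:
                d = k
            if any(s == frozenset({DUMMY}) for s in f.labelset_family()):
                continue
            if not _oracle_acyclic(f, t1, t2):
                continue
            key = f.canonical_key()
            if key not in found:
                found[key] = AgreementForestRecord(
                    forest=f, canonical_key=key, acyclic=True, size=k
                )
        if found:
            maafs = [found[key] for key in sorted(found)]
            return MaafResult(h=k, maafs=maafs, stats={"d": d, "oracle": True})
    raise AssertionError("exhaustive sweep found no acyclic agreement forest")


def oracle_rspr_distance(t1: Forest, t2: Forest) -> int:
    """Brute-force rSPR distance: smallest k-subset of cuts giving an AF."""
    if len(t1.labels) > ORACLE_MAX_LEAVES:
        raise ForestError("instance too large for the exhaustive oracle")
    edges = sorted(t1.parent)
    for k in range(len(edges) + 1):
        for combo in itertools.combinations(edges, k):
            f = _cut_edges(t1, combo)
            if f is not None and size(f) == k and is_af(f, t2):
                return k
    raise AssertionError("no agreement forest found")
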