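"""Bounded agreement-forest search.

Implements the depth-bounded branching search over pairs of forests
``(F1, F2)`` that underlies every computation in this package: the rSPR
distance of two trees (iterative deepening over the budget ``k``), the rSPR
Distance Checking decision procedure (rSPRDC) used as a pruning test, and
the enumeration-mode search that streams agreement forests.

The search repeatedly picks a pair of sibling leaves ``(u, v)`` in ``F2``.
If their counterparts are also siblings in ``F1`` both cherries are merged
into a single leaf carrying the union label set (an in-search subtree
reduction).  Otherwise one of three cases applies:

* **Case 1** - ``u`` and ``v`` lie in different components of ``F1``: branch
  on detaching ``u`` or detaching ``v``.
* **Case 2** (distance/decision mode only) - one of them is the sibling of
  the other's parent in ``F1``: the single forced move detaches the inner
  leaf's sibling.  This shortcut may lose alternative minimum forests, so
  enumeration mode folds it into Case 3.
* **Case 3** - same component, general position: branch on detaching ``u``,
  detaching ``v``, or detaching every pendant subtree hanging off the
  ``u``-``v`` path.

Whenever a detached ``F1`` subtree is a single leaf, the same leaf is
detached in ``F2`` so that the edgeless components of the two forests stay
in one-to-one correspondence (invariants (a)-(c) below).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .forest import (
    Forest,
    ForestError,
    detach,
    merge_sibling_leaves,
    select_sibling_pair,
    size,
)

__all__ = [
    "SearchState",
    "branch_step",
    "check_invariants",
    "rsprdc",
    "rspr_distance",
    "enumerate_agreement_forests",
]


@dataclass
class SearchState:
    """A node of the bounded search tree.

    ``k`` is the number of extra detaching operations still allowed beyond
    the starting forest, whose size was ``k0``; a branch dies as soon as
    ``size(F1) > k + k0``.
    """

    f1: Forest
    f2: Forest
    k: int
    k0: int = 0
    mode: str = "decision"  # "decision" | "enumeration"
    use_h2: bool = False

    @property
    def limit(self) -> int:
        return self.k + self.k0


def check_invariants(f1: Forest, f2: Forest) -> None:
    """Assert the three search invariants.

    (a) size(F1) >= size(F2); (b) all components of F2 except at most one
    are edgeless; (c) every edgeless F2 component has an edgeless F1
    component with an identical label set.
    """
    if size(f1) < size(f2):
        raise AssertionError("invariant (a): size(F1) < size(F2)")
    edged = [r for r in f2.roots() if r in f2.children]
    if len(edged) > 1:
        raise AssertionError("invariant (b): several edged F2 components")
    f1_single = {f1.labels[r] for r in f1.roots() if r in f1.labels}
    for r in f2.roots():
        if r in f2.labels and f2.labels[r] not in f1_single:
            raise AssertionError("invariant (c): unmatched edgeless F2 component")


def _counterpart(f: Forest, labels: frozenset) -> int:
    return f.leaf_by_labelset(labels)


def _merge_all(f1: Forest, f2: Forest) -> None:
    """Exhaustively merge common cherries, in place, in both forests."""
    changed = True
    while changed:
        changed = False
        for u in list(f2.labels):
            if u not in f2.labels or f2.is_root(u):
                continue
            sib = f2.sibling(u)
            if not f2.is_leaf(sib):
                continue
            u1 = _counterpart(f1, f2.labels[u])
            s1 = _counterpart(f1, f2.labels[sib])
            if not f1.is_root(u1) and f1.parent[u1] == f1.parent.get(s1):
                merge_sibling_leaves(f1, u1, s1, in_place=True)
                merge_sibling_leaves(f2, u, sib, in_place=True)
                changed = True


def _find_common_cherry(f1: Forest, f2: Forest) -> Optional[tuple[int, int]]:
    for u in f2.labels:
        if f2.is_root(u):
            continue
        sib = f2.sibling(u)
        if not f2.is_leaf(sib):
            continue
        u1 = _counterpart(f1, f2.labels[u])
        s1 = _counterpart(f1, f2.labels[sib])
        if not f1.is_root(u1) and f1.parent[u1] == f1.parent.get(s1):
            return u, sib
    return None


def _path_pendants(f1: Forest, u1: int, v1: int) -> list[int]:
    """Pendant subtree roots hanging off the undirected u1-v1 path in F1."""
    up = [u1] + f1.ancestors(u1)
    vp = [v1] + f1.ancestors(v1)
    vset = set(vp)
    lca = next(x for x in up if x in vset)
    path = up[: up.index(lca) + 1] + vp[: vp.index(lca)]
    on_path = set(path)
    pendants = [
        (f1.depth(c), c)
        for x in path
        if x in f1.children
        for c in f1.children[x]
        if c not in on_path
    ]
    pendants.sort()  # root-to-leaf along the path, for determinism
    return [c for _, c in pendants]


def _cut_leaf(f1: Forest, f2: Forest, x1: int) -> tuple[Forest, Forest]:
    # x1 may already be a singleton component when the search was started
    # from a proper forest (the generalized problem); then only F2 moves.
    c1 = f1.copy() if f1.is_root(x1) else detach(f1, x1)
    x2 = _counterpart(f2, f1.labels[x1])
    c2 = detach(f2, x2)
    return c1, c2


def _cut_pendants(f1: Forest, f2: Forest, pendants: list[int]) -> tuple[Forest, Forest]:
    c1, c2 = f1.copy(), f2.copy()
    for w in pendants:
        is_leaf = c1.is_leaf(w)
        detach(c1, w, in_place=True)
        if is_leaf:
            w2 = _counterpart(c2, c1.labels[w])
            if not c2.is_root(w2):
                detach(c2, w2, in_place=True)
    return c1, c2


def _branch(
    f1: Forest, f2: Forest, mode: str, use_h2: bool = False
) -> list[tuple[Forest, Forest]]:
    """Child forest pairs for the current state (no merge applies)."""
    pair = select_sibling_pair(f2, f1, use_heuristic2=use_h2)
    u1 = _counterpart(f1, f2.labels[pair.u])
    v1 = _counterpart(f1, f2.labels[pair.v])
    if f1.root_of(u1) != f1.root_of(v1):
        # Case 1: different component trees
        return [_cut_leaf(f1, f2, u1), _cut_leaf(f1, f2, v1)]
    pendants = _path_pendants(f1, u1, v1)
    if mode == "decision" and len(pendants) == 1:
        # Case 2 shortcut: the single forced move
        return [_cut_pendants(f1, f2, pendants)]
    return [
        _cut_leaf(f1, f2, u1),
        _cut_leaf(f1, f2, v1),
        _cut_pendants(f1, f2, pendants),
    ]


def branch_step(state: SearchState) -> list[SearchState]:
    """One step of the bounded search: a forced merge or a case branching."""
    if not state.f1.has_edges():
        return []
    cherry = _find_common_cherry(state.f1, state.f2)
    if cherry is not None:
        u, v = cherry
        f1 = state.f1.copy()
        f2 = state.f2.copy()
        u1 = _counterpart(f1, f2.labels[u])
        v1 = _counterpart(f1, f2.labels[v])
        merge_sibling_leaves(f1, u1, v1, in_place=True)
        merge_sibling_leaves(f2, u, v, in_place=True)
        children = [(f1, f2)]
    else:
        children = _branch(state.f1, state.f2, state.mode, state.use_h2)
    out = []
    for c1, c2 in children:
        check_invariants(c1, c2)
        out.append(
            SearchState(c1, c2, state.k, state.k0, state.mode, state.use_h2)
        )
    return out


# -- decision procedure ------------------------------------------------------


def _decide(f1: Forest, f2: Forest, limit: int) -> bool:
    """Depth-first decision search; mutates its (private) arguments."""
    _merge_all(f1, f2)
    if not f1.has_edges():
        return True
    for c1, c2 in _branch(f1, f2, "decision"):
        if size(c1) > limit:
            continue
        if _decide(c1, c2, limit):
            return True
    return False


def rsprdc(
    t1: Forest,
    t2: Forest,
    k: int,
    f1: Optional[Forest] = None,
    f2: Optional[Forest] = None,
) -> bool:
    """rSPR Distance Checking: can ``k`` more detachings on F1 reach an AF?

    ``f1``/``f2`` default to the trees themselves.  The answer does not
    depend on any heuristic flag; the Case-2 shortcut preserves
    reachability of some minimum agreement forest.
    """
    if k < 0:
        return False
    f1 = t1 if f1 is None else f1
    f2 = t2 if f2 is None else f2
    return _decide(f1.copy(), f2.copy(), size(f1) + k)


def rspr_distance(t1: Forest, t2: Forest) -> int:
    """rSPR distance (= size of a maximum agreement forest).

    Iterative deepening: for k = 0, 1, 2, ... test whether an agreement
    forest of size k exists and return the first success.
    """
    if t1.taxa() != t2.taxa():
        raise ForestError("taxa differ")
    k = 0
    while True:
        if rsprdc(t1, t2, k):
            return k
        k += 1


# -- enumeration-mode stream -------------------------------------------------


def enumerate_agreement_forests(
    t1: Forest,
    t2: Forest,
    k: int,
    f1: Optional[Forest] = None,
    h1: bool = False,
    h2: bool = False,
) -> Iterator[list[frozenset]]:
    """Stream the label-set families of agreement forests within budget.

    Enumeration-mode bounded search from ``(F1, T2)``: no Case-2 shortcut,
    and the search does not stop at the first agreement forest.  Emits the
    family of leaf label sets each time F1 becomes edgeless.  With ``h1``
    the rSPRDC test prunes branches that cannot complete within the
    remaining budget; with ``h2`` sibling pairs are chosen as far apart as
    possible in F1.  Neither flag changes the emitted set.
    """
    f1 = t1 if f1 is None else f1
    limit = size(f1) + k
    yield from _enum(f1.copy(), t2.copy(), limit, h1, h2)


def _enum(
    f1: Forest, f2: Forest, limit: int, h1: bool, h2: bool
) -> Iterator[list[frozenset]]:
    _merge_all(f1, f2)
    if not f1.has_edges():
        yield f1.labelset_family()
        return
    if h1 and not _decide(f1.copy(), f2.copy(), limit):
        return
    for c1, c2 in _branch(f1, f2, "enumeration", h2):
        if size(c1) > limit:
            continue
        yield from _enum(c1, c2, limit, h1, h2)
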