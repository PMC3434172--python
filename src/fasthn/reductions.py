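"""Preprocessing reductions and the end-to-end solving pipeline.

Two MAAF-preserving reductions shrink an instance before the exhaustive
search:

* **Subtree reduction** — a maximal pendant subtree common to both trees is
  collapsed, in both, into a single leaf carrying the union of its taxa.
* **Cluster reduction** — when both trees contain a (non-root, non-leaf)
  node rooting subtrees with the same leaf set, that common cluster is
  split off as an independent subproblem and replaced by a single merged
  leaf in the parents.  Hybridization numbers add across subproblems and
  the MAAF set of the whole instance is the Cartesian product of the
  subproblem MAAF sets.

Clusters are discovered bottom-up (smallest first) and the two reductions
are interleaved until neither applies.  Reductions run only as
preprocessing; during the search itself the merge rule plays the role of
an in-search subtree reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .forest import DUMMY, Forest, ForestError, af_from_labelsets, size
from .maaf import (
    AgreementForestRecord,
    MaafResult,
    _maafs_at_level,
    enumerate_maafs,
    hybridization_number,
)
from .newick import augment_dummy

__all__ = [
    "ReductionLog",
    "ClusterSubproblem",
    "subtree_reduce",
    "cluster_reduce",
    "combine_cluster_results",
    "Solution",
    "solve",
]


@dataclass
class ReductionLog:
    """Ordered record of reduction events, plus the original tree pair.

    Each event is ``("subtree-merge", merged_label_set)`` or
    ``("cluster-split", cluster_label_set, subproblem_index)``.  Label sets
    carry the taxa themselves, so replaying the log (flattening merged
    sets) expands any reduced-space family back to the original taxa.
    """

    events: list = field(default_factory=list)
    original_t1: Optional[Forest] = None
    original_t2: Optional[Forest] = None


@dataclass
class ClusterSubproblem:
    """An independent common-cluster instance split off the input pair."""

    t1_part: Forest
    t2_part: Forest
    cluster_taxa: frozenset


def _common_cherry(t1: Forest, t2: Forest) -> Optional[tuple[int, int, int, int]]:
    sets2 = {}
    for v, s in t2.labels.items():
        if not t2.is_root(v):
            sib = t2.sibling(v)
            if t2.is_leaf(sib):
                sets2[s] = (v, sib)
    for u1, s in t1.labels.items():
        if t1.is_root(u1):
            continue
        sib1 = t1.sibling(u1)
        if not t1.is_leaf(sib1):
            continue
        pair2 = sets2.get(s)
        if pair2 and t2.labels[pair2[1]] == t1.labels[sib1]:
            return u1, sib1, pair2[0], pair2[1]
    return None


def subtree_reduce(t1: Forest, t2: Forest) -> tuple[Forest, Forest, ReductionLog]:
    """Collapse all maximal common pendant subtrees into merged leaves."""
    if t1.taxa() != t2.taxa():
        raise ForestError("taxa differ")
    from .forest import merge_sibling_leaves

    a, b = t1.copy(), t2.copy()
    log = ReductionLog(original_t1=t1, original_t2=t2)
    while True:
        hit = _common_cherry(a, b)
        if hit is None:
            break
        u1, v1, u2, v2 = hit
        merged = a.labels[u1] | a.labels[v1]
        merge_sibling_leaves(a, u1, v1, in_place=True)
        merge_sibling_leaves(b, u2, v2, in_place=True)
        log.events.append(("subtree-merge", merged))
    return a, b, log


def _lowest_common_cluster(t1: Forest, t2: Forest) -> Optional[tuple[int, int]]:
    """Smallest common cluster rooted at non-root internal nodes, if any."""
    by_taxa = {
        t2.subtree_taxa(v): v
        for v in t2.children
        if not t2.is_root(v)
    }
    best = None
    for v1 in t1.children:
        if t1.is_root(v1):
            continue
        taxa = t1.subtree_taxa(v1)
        v2 = by_taxa.get(taxa)
        if v2 is None:
            continue
        key = (len(taxa), tuple(sorted(taxa)))
        if best is None or key < best[0]:
            best = (key, v1, v2)
    return None if best is None else (best[1], best[2])


def _extract_subtree(t: Forest, v: int) -> tuple[Forest, Forest]:
    """Split t at v: (copy of subtree at v, remainder with merged leaf)."""
    sub = Forest()
    mapping = {}
    for x in t.subtree_nodes(v):
        if x in t.labels:
            mapping[x] = sub.add_leaf(t.labels[x])
        else:
            mapping[x] = sub.add_internal()
    for x in t.subtree_nodes(v):
        if x in t.children:
            for c in t.children[x]:
                sub.parent[mapping[c]] = mapping[x]
                sub.children[mapping[x]].append(mapping[c])
    rem = t.copy()
    taxa = t.subtree_taxa(v)
    for x in t.subtree_nodes(v):
        rem.labels.pop(x, None)
        rem.children.pop(x, None)
        if x != v:
            rem.parent.pop(x, None)
    rem.labels[v] = taxa  # the cluster leaf
    return sub, rem


def cluster_reduce(
    t1: Forest, t2: Forest
) -> tuple[list[ClusterSubproblem], ReductionLog]:
    """Split the pair into independent subproblems at common clusters.

    Subproblems are listed innermost-first; the last entry is always the
    outer remainder.  When no common cluster exists the list holds a
    single subproblem identical to the (subtree-reduced) input.
    """
    a, b, log = subtree_reduce(t1, t2)
    subproblems: list[ClusterSubproblem] = []
    while True:
        hit = _lowest_common_cluster(a, b)
        if hit is None:
            break
        v1, v2 = hit
        taxa = a.subtree_taxa(v1)
        sub1, a = _extract_subtree(a, v1)
        sub2, b = _extract_subtree(b, v2)
        subproblems.append(ClusterSubproblem(sub1, sub2, taxa))
        log.events.append(("cluster-split", taxa, len(subproblems) - 1))
        # the merged cluster leaf may enable further subtree reductions
        a, b, inner_log = subtree_reduce(a, b)
        log.events.extend(inner_log.events)
    subproblems.append(ClusterSubproblem(a, b, a.taxa()))
    return subproblems, log


def combine_cluster_results(
    results: list[MaafResult], log: ReductionLog
) -> MaafResult:
    """Cartesian recombination of per-subproblem MAAF sets.

    The total hybridization number is the sum over subproblems.  For each
    choice of one MAAF per subproblem, the inner MAAF's root component
    (the dummy-containing one, dummy stripped) replaces the cluster leaf
    inside the outer component that carries it, and the inner non-root
    components join verbatim.  Records are rebuilt on the original
    dummy-augmented first tree.
    """
    if log.original_t1 is None or len(results) == 0:
        raise ForestError("incomplete cluster results")
    splits = [e for e in log.events if e[0] == "cluster-split"]
    if len(results) != len(splits) + 1:
        raise ForestError("incomplete cluster results")

    # start from the outer remainder (last result), then splice inner
    # subproblems back in reverse split order; families keep the outer dummy
    acc_fams = [rec.forest.labelset_family() for rec in results[-1].maafs]
    for i in range(len(splits) - 1, -1, -1):
        cluster_taxa = splits[i][1]
        inner = results[i]
        new_fams = []
        for outer_fam in acc_fams:
            host_idx = next(
                idx for idx, s in enumerate(outer_fam) if cluster_taxa <= s
            )
            for rec in inner.maafs:
                in_fam = rec.forest.labelset_family()
                in_root = next(s for s in in_fam if DUMMY in s) - {DUMMY}
                in_rest = [s for s in in_fam if DUMMY not in s]
                host = (outer_fam[host_idx] - cluster_taxa) | in_root
                fam = list(outer_fam)
                fam[host_idx] = host
                new_fams.append(fam + in_rest)
        acc_fams = new_fams

    h = sum(r.h for r in results)
    t1_aug = augment_dummy(log.original_t1)
    records: dict[tuple, AgreementForestRecord] = {}
    for fam in acc_fams:
        forest = af_from_labelsets(t1_aug, fam)
        rec = AgreementForestRecord(
            forest=forest,
            canonical_key=forest.canonical_key(),
            acyclic=True,
            size=size(forest),
        )
        if rec.size != h:
            raise AssertionError("cluster combination changed the size")
        records.setdefault(rec.canonical_key, rec)
    maafs = [records[k] for k in sorted(records)]
    return MaafResult(h=h, maafs=maafs, stats={"subproblems": len(results)})


# -- pipeline ----------------------------------------------------------------


@dataclass
class Solution:
    """Result of the full pipeline on an (unaugmented) tree pair."""

    h: int
    maafs: list[AgreementForestRecord]
    t1_aug: Forest
    t2_aug: Forest


def _first_maaf(t1: Forest, t2: Forest, h1: bool, h2: bool) -> MaafResult:
    import itertools as _it

    for k in _it.count():
        for rec in _maafs_at_level(t1, t2, k, h1, h2):
            return MaafResult(h=k, maafs=[rec], stats={"first_only": True})


def solve(
    t1: Forest,
    t2: Forest,
    option: str = "MAAFs",
    cluster: bool = True,
    h1: bool = True,
    h2: bool = True,
) -> Solution:
    """Run reductions, per-subproblem enumeration and recombination.

    ``option`` mirrors the command-line modes: ``HN`` (hybridization
    number only, early exit), ``MAAF`` (one MAAF), ``MAAFs`` (all MAAFs).
    ``cluster`` gates the preprocessing reductions; ``h1``/``h2`` gate the
    search heuristics.  The reported result is invariant under all three
    flags.
    """
    if t1.taxa() != t2.taxa():
        raise ForestError("taxa differ")
    t1_aug, t2_aug = augment_dummy(t1), augment_dummy(t2)

    if option == "HN":
        if cluster:
            subs, _ = cluster_reduce(t1, t2)
            h = sum(
                hybridization_number(augment_dummy(s.t1_part), augment_dummy(s.t2_part), h1, h2)
                for s in subs
            )
        else:
            h = hybridization_number(t1_aug, t2_aug, h1, h2)
        return Solution(h=h, maafs=[], t1_aug=t1_aug, t2_aug=t2_aug)

    first_only = option == "MAAF"
    if cluster:
        subs, log = cluster_reduce(t1, t2)
        results = []
        for s in subs:
            a, b = augment_dummy(s.t1_part), augment_dummy(s.t2_part)
            results.append(
                _first_maaf(a, b, h1, h2) if first_only else enumerate_maafs(a, b, h1, h2)
            )
        combined = combine_cluster_results(results, log)
    else:
        combined = (
            _first_maaf(t1_aug, t2_aug, h1, h2)
            if first_only
            else enumerate_maafs(t1_aug, t2_aug, h1, h2)
        )
        # records are already materialized on the augmented original tree
    maafs = combined.maafs[:1] if first_only else combined.maafs
    return Solution(h=combined.h, maafs=maafs, t1_aug=t1_aug, t2_aug=t2_aug)
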