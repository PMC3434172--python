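"""Hybridization networks from acyclic agreement forests.

A hybridization network here is a rooted DAG (a ``networkx.DiGraph``) in
which every non-leaf node has out-degree 2, exactly one node has in-degree
0, leaves carry a ``label`` attribute, and nodes of in-degree two are the
reticulations.  A network built from an acyclic agreement forest of size
``h`` has exactly ``h`` reticulation nodes and displays both input trees.

Construction.  The network starts as a copy of the first tree, which
already embeds every forest component at its T1 position.  Replaying a
detaching sequence on a working copy of the second tree (components in
reverse topological order of the decision graph) records, for each
component, the node above which it hung in T2 at the moment it was cut
off.  Re-attaching in forward order splices one new junction node per
component into the network immediately above the recorded position and
wires it to the component's root, which thereby acquires a second parent
and becomes a reticulation.  Keeping one in-arc per reticulation and
contracting then yields either tree.
"""

from __future__ import annotations

import itertools
from typing import Optional

import networkx as nx

from .forest import DUMMY, Forest, ForestError, detach, size
from .maaf import AgreementForestRecord, decision_graph

__all__ = [
    "network_from_maaf",
    "displays",
    "extract_forest",
    "network_hybridization_number",
    "network_isomorphic",
]


def _image(tree: Forest, taxa: frozenset) -> int:
    nodes = [v for v, s in tree.labels.items() if s <= taxa]
    return tree.lca(nodes)


def _component_order(forest: Forest, t1: Forest, t2: Forest) -> list[int]:
    """Roots in topological order of the decision graph, dummy first."""
    g = decision_graph(forest, t1, t2).graph
    order = list(
        nx.lexicographical_topological_sort(
            g, key=lambda r: tuple(sorted(forest.subtree_taxa(r)))
        )
    )
    dummy_root = next(r for r in order if DUMMY in forest.subtree_taxa(r))
    if order[0] != dummy_root:
        # the dummy component's root is an ancestor of everything, hence a
        # source; any valid order can start with it
        order.remove(dummy_root)
        order.insert(0, dummy_root)
    return order


def _tree_digraph(t: Forest) -> nx.DiGraph:
    g = nx.DiGraph()
    for v in t.nodes():
        g.add_node(("t1", v))
        if v in t.labels:
            (label,) = t.labels[v]
            g.nodes[("t1", v)]["label"] = label
    for c, p in t.parent.items():
        g.add_edge(("t1", p), ("t1", c))
    return g


def _strip_dummy_network(g: nx.DiGraph) -> None:
    """Remove the dummy leaf and contract the unifurcate nodes it leaves."""
    target = [v for v, d in g.nodes(data=True) if d.get("label") == DUMMY]
    for v in target:
        g.remove_node(v)
    while True:
        uni = [v for v in g.nodes if g.out_degree(v) == 1 and v not in target]
        uni = [v for v in uni if "label" not in g.nodes[v]]
        if not uni:
            break
        for v in uni:
            (c,) = g.successors(v)
            for u in list(g.predecessors(v)):
                g.add_edge(u, c)
            g.remove_node(v)
            break  # re-scan: contractions may cascade


def network_from_maaf(
    record: AgreementForestRecord | Forest, t1: Forest, t2: Forest
) -> nx.DiGraph:
    """One minimum hybridization network for an acyclic agreement forest.

    ``t1`` and ``t2`` are the dummy-augmented input trees; the result has
    the dummy stripped, one reticulation (of in-degree exactly 2) per
    non-root component, and displays both trees.
    """
    forest = record.forest if isinstance(record, AgreementForestRecord) else record
    if not decision_graph(forest, t1, t2).acyclic:
        raise ForestError("input forest not acyclic agreement forest")
    order = _component_order(forest, t1, t2)

    # replay: cut components out of a working copy of t2, deepest-dependency
    # first, recording the sibling node each one leaves behind
    g2 = t2.copy()
    sib: dict[int, int] = {}
    par: dict[int, int] = {}
    for r in reversed(order[1:]):
        taxa = forest.subtree_taxa(r)
        nodes = [v for v, s in g2.labels.items() if s <= taxa]
        rr = g2.lca(nodes)
        if g2.subtree_taxa(rr) != taxa or g2.is_root(rr):
            raise ForestError("input forest not acyclic agreement forest")
        sib[r] = g2.sibling(rr)
        par[r] = g2.parent[rr]
        detach(g2, rr, in_place=True)

    net = _tree_digraph(t1)

    # map every t2 node that can be referenced by a recorded sibling to its
    # node in the network under construction
    pos: dict[int, tuple] = {}
    for r in order:
        for x in forest.subtree_nodes(r):
            taxa = forest.subtree_taxa(x)
            pos[_image(t2, taxa)] = ("t1", _image(t1, taxa))

    t2_in_edge: dict[tuple, tuple] = {}  # reticulation -> its T2-side parent

    for j, r in enumerate(order[1:], start=2):
        y = pos[sib[r]]
        if y in t2_in_edge:
            u = t2_in_edge[y]
        else:
            (u,) = net.predecessors(y)
        junction = ("j", j)
        net.remove_edge(u, y)
        net.add_edge(u, junction)
        net.add_edge(junction, y)
        if y in t2_in_edge:
            t2_in_edge[y] = junction
        ret = ("t1", _image(t1, forest.subtree_taxa(r)))
        net.add_edge(junction, ret)
        t2_in_edge[ret] = junction
        pos[par[r]] = junction

    _strip_dummy_network(net)
    if not nx.is_directed_acyclic_graph(net):
        raise ForestError("constructed network is not acyclic")
    net = nx.convert_node_labels_to_integers(net)
    return net


def network_hybridization_number(net: nx.DiGraph) -> int:
    """Sum over reticulation nodes of (in-degree - 1)."""
    return sum(d - 1 for _, d in net.in_degree() if d >= 2)


def _displayed_trees(net: nx.DiGraph) -> set:
    """Canonical shapes of all trees displayed by the network."""
    retic = [v for v, d in net.in_degree() if d >= 2]
    root = next(v for v, d in net.in_degree() if d == 0)
    taxa_nodes = {v for v, d in net.nodes(data=True) if "label" in d}

    def shape(sub: nx.DiGraph, v) -> Optional[tuple]:
        if "label" in sub.nodes[v]:
            return ("leaf", (sub.nodes[v]["label"],))
        kids = [shape(sub, c) for c in sub.successors(v)]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return ("node",) + tuple(sorted(kids))

    shapes = set()
    for choice in itertools.product(*[list(net.predecessors(v)) for v in retic]):
        sub = net.copy()
        for v, keep in zip(retic, choice):
            for u in list(sub.predecessors(v)):
                if u != keep:
                    sub.remove_edge(u, v)
        reachable = nx.descendants(sub, root) | {root}
        sub.remove_nodes_from(set(sub.nodes) - reachable)
        shapes.add(shape(sub, root))
    return shapes


def displays(net: nx.DiGraph, tree: Forest) -> bool:
    """Does some switching of the network yield this tree?

    Exponential in the number of reticulations; intended for desk-scale
    verification.  A dummy leaf in ``tree`` is ignored, matching networks
    that are emitted dummy-stripped.
    """
    t = tree
    if DUMMY in t.taxa():
        from .newick import strip_dummy

        t = strip_dummy(t)
    net_taxa = {d["label"] for _, d in net.nodes(data=True) if "label" in d}
    if net_taxa != set(map(lambda s: next(iter(s)), t.labels.values())):
        return False
    (root,) = t.roots()
    return t.shape_key(root) in _displayed_trees(net)


def extract_forest(net: nx.DiGraph) -> Forest:
    """The forest left after deleting all edges entering reticulations.

    Nodes without a labelled-leaf descendant are removed and unifurcate
    nodes contracted; for a network built from an agreement forest this
    recovers exactly the source forest's component partition.
    """
    g = net.copy()
    retic = [v for v, d in g.in_degree() if d >= 2]
    for v in retic:
        for u in list(g.predecessors(v)):
            g.remove_edge(u, v)
    # drop nodes with no labelled descendant
    keep = set()
    for v in g.nodes:
        if "label" in g.nodes[v]:
            keep |= nx.ancestors(g, v) | {v}
    g.remove_nodes_from(set(g.nodes) - keep)
    # contract unifurcate nodes
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if g.out_degree(v) == 1 and "label" not in g.nodes[v]:
                (c,) = g.successors(v)
                for u in list(g.predecessors(v)):
                    g.add_edge(u, c)
                g.remove_node(v)
                changed = True
    f = Forest()
    node_map = {}
    for v in nx.topological_sort(g):
        parent = next(iter(g.predecessors(v)), None)
        p = node_map.get(parent)
        if g.out_degree(v) == 0:
            node_map[v] = f.add_leaf({g.nodes[v]["label"]}, p)
        else:
            node_map[v] = f.add_internal(p)
    return f


def network_isomorphic(a: nx.DiGraph, b: nx.DiGraph) -> bool:
    """Exact isomorphism of leaf-labelled networks (VF2 on the DAGs)."""
    nm = nx.algorithms.isomorphism.categorical_node_match("label", None)
    return nx.is_isomorphic(a, b, node_match=nm)
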