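"""Newick and extended-Newick input/output.

Input trees are rooted, binary, semicolon-terminated Newick strings whose
leaf labels use the alphabet ``0-9 a-z A-Z _ .``.  Branch lengths and
internal-node labels are tolerated and discarded (inputs are topologies
only).  Hybridization networks are written in the extended-Newick dialect
with bare ``#Hi`` hybrid tags, which Dendroscope-compatible viewers accept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .forest import DUMMY, Forest, ForestError

__all__ = [
    "NewickDocument",
    "NewickError",
    "parse_newick",
    "write_newick",
    "write_enewick",
    "parse_enewick",
    "augment_dummy",
    "strip_dummy",
    "validate_label",
]

LABEL_RE = re.compile(r"[0-9A-Za-z_.]+")


class NewickError(ValueError):
    """Malformed Newick input.  Carries the character offset of the fault."""

    def __init__(self, message: str, offset: Optional[int] = None) -> None:
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


@dataclass(frozen=True)
class NewickDocument:
    """One Newick tree description, with its provenance."""

    text: str
    source: str = "<literal>"

    @classmethod
    def from_file(cls, path: str) -> "NewickDocument":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(fh.read(), source=path)


def validate_label(label: str, offset: Optional[int] = None) -> str:
    if not label or not LABEL_RE.fullmatch(label):
        raise NewickError(f"illegal label {label!r}", offset)
    return label


class _Parser:
    """Recursive-descent parser for the restricted Newick grammar."""

    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickError:
        return NewickError(msg, self.pos)

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def label(self, required: bool = True) -> str:
        self._skip_ws()
        m = LABEL_RE.match(self.text, self.pos)
        if not m:
            if required:
                raise self.error("expected a label")
            return ""
        self.pos = m.end()
        return m.group()

    def skip_annotations(self) -> None:
        """Consume an optional internal label and/or branch length."""
        self.label(required=False)
        if self.peek() == ":":
            self.pos += 1
            m = re.compile(r"[-+0-9.eE]+").match(self.text, self.pos)
            if not m:
                raise self.error("expected a branch length")
            self.pos = m.end()

    def subtree(self, forest: Forest, parent: Optional[int]) -> int:
        if self.peek() == "(":
            self.pos += 1
            node = forest.add_internal(parent)
            n_children = 0
            while True:
                self.subtree(forest, node)
                n_children += 1
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise self.error("expected ',' or ')'")
            if n_children != 2:
                raise NewickError("tree not binary", self.pos)
            self.skip_annotations()
            return node
        start = self.pos
        name = self.label(required=False)
        if not name:
            raise self.error("expected a label or '('")
        leaf = forest.add_leaf({name}, parent)
        # leaf may carry a branch length
        if self.peek() == ":":
            self.pos += 1
            m = re.compile(r"[-+0-9.eE]+").match(self.text, self.pos)
            if not m:
                raise self.error("expected a branch length")
            self.pos = m.end()
        forest.labels[leaf] = frozenset({validate_label(name, start)})
        return leaf

    def parse(self) -> Forest:
        forest = Forest()
        self.subtree(forest, None)
        self.expect(";")
        self._skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing text after ';'")
        seen: set = set()
        for s in forest.labels.values():
            (name,) = s
            if name in seen:
                raise NewickError(f"duplicate taxon {name!r}")
            seen.add(name)
        return forest


def parse_newick(doc: NewickDocument | str) -> Forest:
    """Parse one rooted binary tree; returns a one-component forest."""
    text = doc.text if isinstance(doc, NewickDocument) else doc
    return _Parser(text).parse()


def _render(forest: Forest, v: int) -> str:
    if forest.is_leaf(v):
        s = forest.labels[v]
        if len(s) != 1:
            raise ForestError("cannot serialize a merged leaf as Newick")
        (name,) = s
        return "rho" if name == DUMMY else name
    a, b = forest.ordered_children(v)
    return f"({_render(forest, a)},{_render(forest, b)})"


def write_newick(forest: Forest) -> str:
    """Serialize a one-component forest in canonical order.

    Children are ordered by their smallest descendant label, so equal
    topologies always produce byte-identical strings.
    """
    roots = forest.roots()
    if len(roots) != 1:
        raise ForestError("cannot serialize forest as single Newick tree")
    return _render(forest, roots[0]) + ";"


def augment_dummy(tree: Forest) -> Forest:
    """Attach a dummy leaf beside the old root, under a fresh root.

    The standard preprocessing for agreement-forest computations: the new
    root's children are the old root and the reserved dummy leaf, which
    anchors the root components of both trees.
    """
    if DUMMY in tree.taxa():
        raise ForestError("tree is already dummy-augmented")
    (old_root,) = tree.roots()
    t = tree.copy()
    new_root = t.add_internal()
    t.parent[old_root] = new_root
    t.children[new_root].append(old_root)
    t.add_leaf({DUMMY}, new_root)
    return t


def strip_dummy(tree: Forest) -> Forest:
    """Inverse of :func:`augment_dummy` on a one-component tree."""
    t = tree.copy()
    leaf = t.leaf_by_labelset(frozenset({DUMMY}))
    root = t.parent[leaf]
    other = t.sibling(leaf)
    del t.labels[leaf], t.parent[leaf], t.parent[other]
    del t.children[root]
    return t


# -- extended Newick for networks -------------------------------------------


def write_enewick(network: nx.DiGraph) -> str:
    """Serialize a hybridization network in extended Newick.

    Reticulation nodes (in-degree 2) appear twice under a shared ``#Hi``
    tag; the occurrence reached first in the deterministic traversal carries
    the node's children.  Leaf nodes have a ``label`` attribute.
    """
    retic = [v for v in network.nodes if network.in_degree(v) >= 2]
    for v in retic:
        if network.in_degree(v) != 2:
            raise ForestError("non-binary reticulation")
    roots = [v for v in network.nodes if network.in_degree(v) == 0]
    if len(roots) != 1:
        raise ForestError("network must have exactly one root")

    min_label: dict = {}

    def mn(v) -> str:
        if v in min_label:
            return min_label[v]
        min_label[v] = "￿"  # placeholder against reticulation re-entry
        succ = list(network.successors(v))
        if not succ:
            out = network.nodes[v]["label"]
        else:
            out = min(mn(c) for c in succ)
        min_label[v] = out
        return out

    tags: dict = {}
    expanded: set = set()

    def render(v) -> str:
        is_retic = network.in_degree(v) >= 2
        tag = ""
        if is_retic:
            if v not in tags:
                tags[v] = f"#H{len(tags) + 1}"
            tag = tags[v]
            if v in expanded:
                return tag
            expanded.add(v)
        succ = sorted(network.successors(v), key=mn)
        if not succ:
            return network.nodes[v]["label"] + tag
        inner = ",".join(render(c) for c in succ)
        return f"({inner}){tag}"

    return render(roots[0]) + ";"


def parse_enewick(text: str) -> nx.DiGraph:
    """Re-parse an extended Newick string into a network DiGraph."""
    g = nx.DiGraph()
    counter = [0]

    def fresh() -> int:
        counter[0] += 1
        return counter[0]

    hybrids: dict[str, int] = {}
    p = _Parser(text)

    def node_for_tag(tag: str) -> int:
        if tag not in hybrids:
            hybrids[tag] = fresh()
            g.add_node(hybrids[tag])
        return hybrids[tag]

    def subtree(parent: Optional[int]) -> None:
        if p.peek() == "(":
            p.pos += 1
            node = fresh()
            g.add_node(node)
            while True:
                subtree(node)
                ch = p.peek()
                if ch == ",":
                    p.pos += 1
                    continue
                if ch == ")":
                    p.pos += 1
                    break
                raise p.error("expected ',' or ')'")
            if p.peek() == "#":
                m = re.compile(r"#H\d+").match(p.text, p.pos)
                if not m:
                    raise p.error("malformed hybrid tag")
                p.pos = m.end()
                tagged = node_for_tag(m.group())
                # transfer children to the shared hybrid node
                for c in list(g.successors(node)):
                    g.add_edge(tagged, c)
                    g.remove_edge(node, c)
                g.remove_node(node)
                node = tagged
            if parent is not None:
                g.add_edge(parent, node)
            return
        if p.peek() == "#":
            m = re.compile(r"#H\d+").match(p.text, p.pos)
            if not m:
                raise p.error("malformed hybrid tag")
            p.pos = m.end()
            node = node_for_tag(m.group())
            if parent is not None:
                g.add_edge(parent, node)
            return
        name = p.label(required=True)
        tag = None
        if p.peek() == "#":
            m = re.compile(r"#H\d+").match(p.text, p.pos)
            if not m:
                raise p.error("malformed hybrid tag")
            p.pos = m.end()
            tag = m.group()
        node = node_for_tag(tag) if tag else fresh()
        g.add_node(node)
        g.nodes[node]["label"] = name
        if parent is not None:
            g.add_edge(parent, node)

    subtree(None)
    p.expect(";")
    return g
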