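"""Rooted reference phylogeny with stable edge keys.

The tree is stored as flat parent/children arrays; every non-root node
identifies the edge to its parent, so "edge id" == child node id. Newick
parsing is delegated to dendropy; writing is done locally so that branch
lengths round-trip exactly and jplace-style ``{edge_num}`` annotations can
be emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


class NewickError(ValueError):
    pass


@dataclass
class ReferencePhylogeny:
    parent: np.ndarray          # int, -1 at root
    lengths: np.ndarray         # float branch length of edge above each node
    labels: list                # str leaf label or None for internal nodes
    children: list = field(default_factory=list)  # list[list[int]]

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    self.children[p].append(i)
        roots = [i for i, p in enumerate(self.parent) if p < 0]
        if len(roots) != 1:
            raise NewickError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        if not np.all(np.isfinite(self.lengths[np.arange(n) != self.root])):
            raise NewickError("branch lengths must be finite")
        if np.any(self.lengths[np.arange(n) != self.root] < 0):
            raise NewickError("branch lengths must be >= 0")
        labs = [l for l in self.labels if l is not None]
        if len(labs) != len(set(labs)):
            dup = sorted({l for l in labs if labs.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {', '.join(dup)}")

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def leaves(self) -> list:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_labels(self) -> list:
        return [self.labels[i] for i in self.leaves]

    @property
    def edges(self) -> list:
        """Edge ids (== child node ids), in node order; excludes the root."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def postorder(self) -> list:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def preorder(self) -> list:
        return self.postorder()[::-1]

    def leaves_below(self, node: int) -> list:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)

    def total_length(self) -> float:
        return float(sum(self.lengths[e] for e in self.edges))

    # -- conversion ------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "ReferencePhylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise NewickError("unlabeled leaf")
                labels[i] = nd.taxon.label.replace(" ", "_")
        return cls(parent=parent, lengths=lengths, labels=labels)

    def to_dendropy(self) -> "dendropy.Tree":
        return dendropy.Tree.get(data=write_newick(self), schema="newick",
                                 preserve_underscores=True)


def read_newick(text: str) -> ReferencePhylogeny:
    """Parse a Newick string into a ReferencePhylogeny.

    Raises NewickError (with the parser's position information where
    available) on malformed input or duplicate leaf labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc
    return ReferencePhylogeny.from_dendropy(dtree)


def _fmt_length(x: float) -> str:
    return repr(float(x))


def write_newick(tree: ReferencePhylogeny, edge_numbers: dict | None = None) -> str:
    """Serialise to Newick; branch lengths use shortest exact-round-trip reprs.

    When ``edge_numbers`` maps edge id -> integer, jplace-style ``{n}``
    annotations are appended after each branch length.
    """
    def render(node: int) -> str:
        if tree.is_leaf(node):
            s = tree.labels[node]
        else:
            s = "(" + ",".join(render(c) for c in tree.children[node]) + ")"
        if node != tree.root:
            s += ":" + _fmt_length(tree.lengths[node])
            if edge_numbers is not None:
                s += "{%d}" % edge_numbers[node]
        return s

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        return render(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def edge_numbering(tree: ReferencePhylogeny) -> dict:
    """Deterministic bijection edge id -> 0-based edge number (preorder)."""
    return {e: i for i, e in enumerate(v for v in tree.preorder() if v != tree.root)}


def reroot_on_edge(tree: ReferencePhylogeny, leaf_label: str) -> ReferencePhylogeny:
    """Reroot the tree on the terminal edge of the given leaf (midpoint of it).

    Used to verify likelihood invariance under re-rooting of a reversible
    model; delegates the topological surgery to dendropy.
    """
    dtree = tree.to_dendropy()
    nd = None
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon.label == leaf_label:
            nd = leaf
    if nd is None:
        raise KeyError(leaf_label)
    half = (nd.edge.length or 0.0) / 2.0
    dtree.reroot_at_edge(nd.edge, length1=half, length2=half,
                         update_bipartitions=False)
    return ReferencePhylogeny.from_dendropy(dtree)
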