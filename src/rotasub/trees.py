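"""Thin tree layer: Newick I/O via dendropy plus an indexed array view.

Branch lengths are in expected substitutions per site (superscaled units when
used with superscaled models). Trees are treated as rooted at the dendropy
seed node; for reversible models the likelihood does not depend on that
choice (pulley principle).
"""

from __future__ import annotations

import io

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal Newick string."""
    if source.lstrip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(path=source, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", unquoted_underscores=True,
                       suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


class IndexedTree:
    """Array-indexed rooted view of a dendropy tree for fast traversal.

    Node 0 is the root (seed node); ``edge_length[v]`` is the branch above
    node ``v`` (0 for the root). Unlabelled internal nodes receive generated
    labels ``node<k>`` so that ancestral states can be addressed.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(self._nodes)}
        n = len(self._nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.edge_length = np.zeros(n)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.labels: list[str] = [""] * n
        self.is_leaf = np.zeros(n, dtype=bool)
        auto = 0
        for i, nd in enumerate(self._nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                if nd.edge.length is not None:
                    if nd.edge.length < 0:
                        raise TreeError(f"negative branch length {nd.edge.length}")
                    self.edge_length[i] = float(nd.edge.length)
            if nd.is_leaf():
                self.is_leaf[i] = True
                self.labels[i] = nd.taxon.label
            else:
                if nd.label:
                    self.labels[i] = nd.label
                else:
                    self.labels[i] = f"node{auto}"
                    auto += 1
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise TreeError(f"duplicate node labels: {dupes}")
        self.by_label = {l: i for i, l in enumerate(self.labels)}
        self.postorder = [index[id(nd)] for nd in tree.postorder_node_iter()]
        self.preorder = list(range(n))
        self.leaves = np.flatnonzero(self.is_leaf)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def leaf_label_list(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def set_edge_lengths(self, lengths: np.ndarray) -> None:
        """Write branch lengths back onto the underlying dendropy tree."""
        self.edge_length = np.asarray(lengths, dtype=float).copy()
        for i, nd in enumerate(self._nodes):
            if nd.parent_node is not None:
                nd.edge.length = float(self.edge_length[i])

    def total_length(self) -> float:
        return float(self.edge_length.sum())


def as_indexed(tree) -> IndexedTree:
    return tree if isinstance(tree, IndexedTree) else IndexedTree(tree)
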