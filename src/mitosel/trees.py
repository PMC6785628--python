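"""Rooted tree container for likelihood computations.

Parsing is delegated to dendropy; this module flattens the tree into arrays
(parent pointers, postorder) that the pruning code consumes, and handles the
CODEML-style ``#k`` foreground-branch tags, which are not standard Newick and
are stripped from labels after parsing.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


_FG_TAG = re.compile(r"\s*#\s*(\d+)\s*$")


@dataclass
class PhyloTree:
    """A rooted tree as flat arrays.

    Nodes are indexed 0..n_nodes-1; ``parent[root] == -1``.  ``postorder``
    lists every node after all of its descendants.  ``branch_length[i]`` is
    the length of the branch above node i (0.0 above the root).  ``foreground``
    marks branches carrying a ``#k`` tag (the branch above the tagged node).
    """

    parent: np.ndarray
    children: list[list[int]]
    branch_length: np.ndarray
    labels: list[str | None]          # leaf taxon names; internal may be None
    foreground: np.ndarray            # bool per node (branch above node)
    postorder: np.ndarray = field(init=False)
    root: int = field(init=False)

    def __post_init__(self):
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if np.any(self.branch_length < 0):
            raise TreeError("negative branch length")
        order: list[int] = []
        stack = [self.root]
        seen = 0
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
            seen += 1
        if seen != self.n_nodes:
            raise TreeError("disconnected nodes in tree")
        self.postorder = np.asarray(order[::-1], dtype=np.intp)

    # -- basic queries -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def node_of_label(self, label: str) -> int:
        for i, lab in enumerate(self.labels):
            if lab == label:
                return i
        raise TreeError(f"no node labelled {label!r}")

    def foreground_nodes(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.foreground)]

    def subtree_leaves(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            stack.extend(self.children[v])
        return out

    def is_ancestor(self, anc: int, node: int) -> bool:
        """True if `anc` lies on the root path of `node` (strictly above it)."""
        v = self.parent[node]
        while v >= 0:
            if v == anc:
                return True
            v = self.parent[v]
        return False

    def on_same_path(self, a: int, b: int) -> bool:
        return self.is_ancestor(a, b) or self.is_ancestor(b, a)

    def total_length(self) -> float:
        return float(self.branch_length.sum())

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            branch_length=self.branch_length.copy(),
            labels=list(self.labels),
            foreground=self.foreground.copy(),
        )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise TreeError(f"could not parse Newick: {exc}") from exc

        nodes = list(dtree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.intp)
        children: list[list[int]] = [[] for _ in nodes]
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        fg = np.zeros(len(nodes), dtype=bool)

        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
            if n.edge.length is not None:
                lengths[i] = float(n.edge.length)
            raw = n.taxon.label if n.taxon is not None else n.label
            if raw is not None:
                m = _FG_TAG.search(raw)
                if m:
                    fg[i] = True
                    raw = raw[: m.start()]
                labels[i] = raw or None
        return cls(parent=parent, children=children, branch_length=lengths,
                   labels=labels, foreground=fg)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: int) -> str:
            lab = self.labels[node] or ""
            if not self.is_leaf(node):
                lab = "(" + ",".join(fmt(c) for c in self.children[node]) + ")" + lab
            if self.foreground[node]:
                lab += "#1"
            if lengths and self.parent[node] >= 0:
                lab += f":{self.branch_length[node]:.10g}"
            return lab

        return fmt(self.root) + ";"

    def write(self, path, lengths: bool = True) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(lengths=lengths) + "\n")


def star_tree(labels: list[str], branch_length: float = 0.0) -> PhyloTree:
    """A root joined directly to every leaf (handy in tests/degenerate cases)."""
    n = len(labels)
    parent = np.concatenate([[-1], np.zeros(n, dtype=np.intp)]).astype(np.intp)
    children = [list(range(1, n + 1))] + [[] for _ in range(n)]
    return PhyloTree(
        parent=parent,
        children=children,
        branch_length=np.concatenate([[0.0], np.full(n, branch_length)]),
        labels=[None] + list(labels),
        foreground=np.zeros(n + 1, dtype=bool),
    )
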