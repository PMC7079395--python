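"""Rooted cell-type trees with branch lengths in SSE units.

Branch lengths are measured in expected single-site events per CpG, the
model's time unit.  Every node carries a unique name; internal nodes must
be labeled in the Newick string when internal methylation states are
observed.  A branch is identified by its child node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Tree"]


@dataclass
class Tree:
    """Rooted tree stored as parent-pointer arrays.

    Attributes
    ----------
    names : list of str
        Unique node names, index-aligned with all arrays.
    parent : numpy.ndarray of int
        Parent node index; -1 for the root.
    lengths : numpy.ndarray of float
        Length of the branch above each node (SSE units); 0 at the root.
    """

    names: list
    parent: np.ndarray
    lengths: np.ndarray

    # Derived, filled in __post_init__.
    root: int = field(init=False)
    children: list = field(init=False)
    postorder: np.ndarray = field(init=False)
    preorder: np.ndarray = field(init=False)
    branch_nodes: np.ndarray = field(init=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("node names must be unique")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        bad = [self.names[i] for i in range(n) if i != self.root and not self.lengths[i] > 0]
        if bad:
            raise ValueError(f"branch lengths must be positive; offending nodes: {bad}")
        self.children = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        pre = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            pre.append(node)
            stack.extend(reversed(self.children[node]))
        if len(pre) != n:
            raise ValueError("tree contains a cycle or disconnected nodes")
        self.preorder = np.asarray(pre, dtype=np.int64)
        self.postorder = self.preorder[::-1].copy()
        self.branch_nodes = np.asarray(
            [i for i in pre if i != self.root], dtype=np.int64
        )

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    @property
    def total_length(self) -> float:
        return float(self.lengths[self.branch_nodes].sum())

    def is_tip(self, node: int) -> bool:
        return len(self.children[node]) == 0

    @property
    def tips(self) -> np.ndarray:
        return np.asarray([i for i in range(self.n_nodes) if self.is_tip(i)], dtype=np.int64)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def branch_names(self) -> list:
        """Names of branch child nodes, in canonical branch order (preorder)."""
        return [self.names[i] for i in self.branch_nodes]

    def with_lengths(self, lengths_by_branch: np.ndarray) -> "Tree":
        """Copy of the tree with branch lengths given in canonical branch order."""
        new = self.lengths.copy()
        new[self.branch_nodes] = lengths_by_branch
        return Tree(list(self.names), self.parent.copy(), new)

    # -- Newick I/O -------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        """Parse a Newick string (internal node labels preserved)."""
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        names, parent, lengths = [], [], []
        index = {}
        unnamed = 0
        for node in dtree.preorder_node_iter():
            if node.taxon is not None:
                name = node.taxon.label
            elif node.label:
                name = node.label
            else:
                name = f"node{unnamed}"
                unnamed += 1
            index[id(node)] = len(names)
            names.append(name)
            if node.parent_node is None:
                parent.append(-1)
                lengths.append(0.0)
            else:
                parent.append(index[id(node.parent_node)])
                if node.edge.length is None:
                    raise ValueError(f"branch above node {name!r} has no length")
                lengths.append(float(node.edge.length))
        return cls(names, np.asarray(parent), np.asarray(lengths))

    def to_newick(self) -> str:
        """Serialize with full-precision branch lengths (round-trip exact)."""

        def render(node: int) -> str:
            label = self.names[node]
            if self.children[node]:
                inner = ",".join(render(c) for c in self.children[node])
                label = f"({inner}){label}"
            if node == self.root:
                return label
            return f"{label}:{float(self.lengths[node])!r}"

        return render(self.root) + ";"

    @classmethod
    def balanced_quartet(cls, lengths=None) -> "Tree":
        """The 4-tip tree ((A,B)AB,(C,D)CD)root used in reduced simulation designs."""
        newick = "((A:1,B:1)AB:1,(C:1,D:1)CD:1)root;"
        tree = cls.from_newick(newick)
        if lengths is not None:
            tree = tree.with_lengths(np.asarray(lengths, dtype=float))
        return tree
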