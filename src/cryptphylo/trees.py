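"""Rooted trees over crypt samples.

A light array-backed rooted tree.  Leaves are numbered ``0 .. n_leaves-1``
and carry sample names; every non-root node identifies the branch above it,
so "branch i" always means the edge from ``parent[i]`` down to node ``i``.
Branch lengths are stored in ``length`` (time-fractions for simulated
trees, assigned mutation counts for inferred phylogenies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Tree", "rf_distance"]


@dataclass
class Tree:
    parent: np.ndarray                 # parent[i] node id, -1 at the root
    leaf_names: list[str]              # names of leaves 0..n_leaves-1
    length: np.ndarray | None = None   # branch length above each node
    support: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        if self.length is None:
            self.length = np.zeros(self.n_nodes)
        self.length = np.asarray(self.length, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def postorder(self) -> list[int]:
        ch = self.children()
        out: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(ch[node])
        out.reverse()
        return out

    def branches(self) -> np.ndarray:
        """Ids of all non-root nodes (each names the branch above it)."""
        return np.flatnonzero(self.parent >= 0)

    def leafsets(self) -> np.ndarray:
        """Bitmask of descendant leaves per node (leaf i -> bit i)."""
        masks = np.zeros(self.n_nodes, dtype=np.uint64)
        for node in self.postorder():
            if node < self.n_leaves:
                masks[node] = np.uint64(1) << np.uint64(node)
            if self.parent[node] >= 0:
                masks[self.parent[node]] |= masks[node]
        return masks

    def clades(self) -> set[frozenset[str]]:
        """Leaf-name sets of internal, non-root nodes (rooted clades)."""
        masks = self.leafsets()
        out: set[frozenset[str]] = set()
        for node in range(self.n_nodes):
            if node < self.n_leaves or node == self.root:
                continue
            names = [self.leaf_names[i] for i in range(self.n_leaves)
                     if masks[node] >> np.uint64(i) & np.uint64(1)]
            out.add(frozenset(names))
        return out

    def depths(self) -> np.ndarray:
        """Root-to-node path length sums."""
        d = np.zeros(self.n_nodes)
        for node in self.postorder()[::-1]:
            if self.parent[node] >= 0:
                d[node] = d[self.parent[node]] + self.length[node]
        return d

    # -- serialization -----------------------------------------------------
    def newick(self, lengths: bool = True, supports: bool = False) -> str:
        ch = self.children()

        def sub(node: int) -> str:
            if node < self.n_leaves:
                label = self.leaf_names[node]
            else:
                inner = ",".join(sorted(sub(c) for c in ch[node]))
                sup = ""
                if supports and node in self.support:
                    sup = f"{self.support[node]:g}"
                label = f"({inner}){sup}"
            if lengths and self.parent[node] >= 0:
                label += f":{self.length[node]:g}"
            return label

        return sub(self.root) + ";"

    def canonical_newick(self) -> str:
        """Topology-only Newick with children sorted; a canonical key."""
        return self.newick(lengths=False)

    def copy(self) -> "Tree":
        t = Tree(self.parent.copy(), list(self.leaf_names), self.length.copy())
        t.support = dict(self.support)
        return t


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds distance between two rooted trees: size of the
    symmetric difference of their internal (non-root) clade sets."""
    if set(a.leaf_names) != set(b.leaf_names):
        raise ValueError("trees must share a leaf set")
    return len(a.clades() ^ b.clades())
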