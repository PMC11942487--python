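"""Rooted binary dendrograms: average-linkage clustering, Newick I/O, clades.

A :class:`Dendrogram` stores a strictly binary rooted merge tree over gene
leaves. Leaves sit at height 0 and every internal node carries its merge
height (TOM-distance units), non-decreasing along each leaf-to-root path
(average linkage is monotone). Newick branch lengths encode height
differences (parent height − own height), so leaf-to-root path lengths equal
the root height and a scale bar on the tree reads in TOM distance.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = ["Dendrogram", "average_linkage"]

_NEWICK_META = set("(),:;[]' \t\n")


class Dendrogram:
    """Strictly binary rooted tree with per-node heights.

    Nodes are integer ids: ``0 .. n-1`` are leaves (in ``leaf_names`` order),
    ``n .. 2n-2`` are internal nodes ordered by non-decreasing height, with
    ``2n-2`` the root.
    """

    def __init__(
        self,
        leaf_names: list[str],
        children: np.ndarray,
        heights: np.ndarray,
    ) -> None:
        n = len(leaf_names)
        if n < 2:
            raise ValueError("a dendrogram needs at least 2 leaves")
        if len(set(leaf_names)) != n:
            raise ValueError("leaf names must be unique")
        self.leaf_names = [str(x) for x in leaf_names]
        self.children = np.asarray(children, dtype=np.intp)  # (2n-1, 2); -1 for leaves
        self.heights = np.asarray(heights, dtype=np.float64)  # (2n-1,)
        if self.children.shape != (2 * n - 1, 2) or self.heights.shape != (2 * n - 1,):
            raise ValueError("inconsistent node arrays")
        self.n_leaves = n
        self.parent = np.full(2 * n - 1, -1, dtype=np.intp)
        for v in range(n, 2 * n - 1):
            l, r = self.children[v]
            if l < 0 or r < 0:
                raise ValueError(f"internal node {v} missing a child")
            if self.parent[l] != -1 or self.parent[r] != -1:
                raise ValueError("node with two parents")
            self.parent[l] = self.parent[r] = v
        self.root = 2 * n - 2
        if self.parent[self.root] != -1:
            raise ValueError("root must have no parent")
        self._index = {name: i for i, name in enumerate(self.leaf_names)}
        # monotone heights along every path
        hp = self.heights[self.parent[: self.root]]
        if np.any(hp < self.heights[: self.root] - 1e-9):
            raise ValueError("heights must be non-decreasing toward the root")
        # subtree leaf counts
        self.leaf_count = np.ones(2 * n - 1, dtype=np.intp)
        for v in range(n, 2 * n - 1):
            l, r = self.children[v]
            self.leaf_count[v] = self.leaf_count[l] + self.leaf_count[r]
        if self.leaf_count[self.root] != n:
            raise ValueError("tree is not connected")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_linkage(cls, Z: np.ndarray, leaf_names: list[str]) -> "Dendrogram":
        """Build from a scipy linkage matrix (merges in height order)."""
        Z = np.asarray(Z, dtype=np.float64)
        n = len(leaf_names)
        children = np.full((2 * n - 1, 2), -1, dtype=np.intp)
        heights = np.zeros(2 * n - 1)
        for i in range(n - 1):
            children[n + i] = (int(Z[i, 0]), int(Z[i, 1]))
            heights[n + i] = Z[i, 2]
        return cls(leaf_names, children, heights)

    @classmethod
    def from_newick(cls, text: str) -> "Dendrogram":
        """Parse a rooted binary Newick string with branch lengths.

        Node heights are recovered as the maximum downstream path length,
        which reproduces the original heights for ultrametric trees.
        Polytomies and negative branch lengths are rejected.
        """
        import dendropy

        text = text.strip()
        if not text.endswith(";"):
            raise ValueError(
                f"newick parse error at position {len(text)}: missing terminal ';'"
            )
        try:
            t = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise ValueError(f"newick parse error: {exc}") from exc

        leaves: list[str] = []
        children: list[tuple[int, int]] = []
        node_h: list[float] = []  # parallel: internal node heights
        internal_nodes: list[tuple[float, int, int]] = []

        def walk(node) -> tuple[int, float]:
            """Return (temp id, height); leaves get ids 0.., internals later."""
            kids = node.child_nodes()
            if not kids:
                label = node.taxon.label if node.taxon else (node.label or "")
                if not label:
                    raise ValueError("newick parse error: unlabeled leaf")
                leaves.append(str(label))
                return len(leaves) - 1, 0.0
            if len(kids) != 2:
                raise ValueError(
                    f"non-binary node with {len(kids)} children: "
                    "only strictly binary trees are supported"
                )
            sub = []
            h = 0.0
            for kid in kids:
                cid, ch = walk(kid)
                bl = kid.edge.length
                if bl is None:
                    raise ValueError("newick parse error: missing branch length")
                if bl < 0:
                    raise ValueError("negative branch length")
                sub.append(cid)
                h = max(h, ch + float(bl))
            internal_nodes.append((h, sub[0], sub[1]))
            return -len(internal_nodes), h  # negative temp id for internals

        root = t.seed_node
        if len(root.child_nodes()) == 1:
            root = root.child_nodes()[0]
        walk(root)
        n = len(leaves)
        if len(internal_nodes) != n - 1:
            raise ValueError("tree is not a single binary tree")
        # order internal nodes by height; remap temp ids
        order = sorted(range(len(internal_nodes)), key=lambda i: internal_nodes[i][0])
        remap = {-(i + 1): n + rank for rank, i in enumerate(order)}

        def resolve(cid: int) -> int:
            return cid if cid >= 0 else remap[cid]

        children_arr = np.full((2 * n - 1, 2), -1, dtype=np.intp)
        heights = np.zeros(2 * n - 1)
        for rank, i in enumerate(order):
            h, a, b = internal_nodes[i]
            children_arr[n + rank] = (resolve(a), resolve(b))
            heights[n + rank] = h
        return cls(leaves, children_arr, heights)

    # -- queries -----------------------------------------------------------

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    def leaf_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            close = [g for g in self.leaf_names if name.lower() in g.lower()][:5]
            raise KeyError(f"unknown leaf {name!r}; close matches: {close}") from None

    def leaf_set(self, node: int) -> list[str]:
        """Descendant leaf names of ``node`` in leaf-index order."""
        return [self.leaf_names[i] for i in sorted(self._leaf_ids(node))]

    def _leaf_ids(self, node: int) -> list[int]:
        if not (0 <= node < 2 * self.n_leaves - 1):
            raise KeyError(f"unknown node id {node}")
        stack, out = [int(node)], []
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def ancestors(self, leaf: str) -> list[int]:
        """Internal nodes on the path from the leaf's parent to the root."""
        v = self.leaf_index(leaf)
        out = []
        while self.parent[v] != -1:
            v = int(self.parent[v])
            out.append(v)
        return out

    def internal_heights(self, node: int) -> np.ndarray:
        """Heights of all internal nodes in the subtree rooted at ``node``."""
        stack, out = [int(node)], []
        while stack:
            v = stack.pop()
            if not self.is_leaf(v):
                out.append(self.heights[v])
                stack.extend(self.children[v])
        return np.sort(np.asarray(out))

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """(left, right, height) triples for internal nodes in id order."""
        return [
            (int(self.children[v, 0]), int(self.children[v, 1]), float(self.heights[v]))
            for v in range(self.n_leaves, 2 * self.n_leaves - 1)
        ]

    # -- newick ------------------------------------------------------------

    def to_newick(self, node: int | None = None) -> str:
        """Serialize the subtree at ``node`` (default root) to Newick.

        Branch lengths are height differences; the subtree root carries no
        branch length and the string is ';'-terminated.
        """
        node = self.root if node is None else int(node)
        for name in (self.leaf_names[i] for i in self._leaf_ids(node)):
            if set(name) & _NEWICK_META:
                raise ValueError(f"leaf label {name!r} contains Newick metacharacters")
        buf = _io.StringIO()

        def emit(v: int, parent_h: float | None) -> None:
            if self.is_leaf(v):
                buf.write(self.leaf_names[v])
            else:
                buf.write("(")
                emit(int(self.children[v, 0]), float(self.heights[v]))
                buf.write(",")
                emit(int(self.children[v, 1]), float(self.heights[v]))
                buf.write(")")
            if parent_h is not None:
                bl = parent_h - (0.0 if self.is_leaf(v) else float(self.heights[v]))
                buf.write(f":{bl!r}")  # shortest exact round-trip decimal

        emit(node, None)
        buf.write(";")
        return buf.getvalue()


def average_linkage(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """UPGMA-style unweighted average-linkage clustering of a distance matrix.

    Inter-cluster distance is the arithmetic mean over all cross pairs.
    Merge order on exact ties follows scipy's deterministic nearest-neighbor
    chain, so repeated runs are bit-reproducible.
    """
    d = np.asarray(dist, dtype=np.float64)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if d.shape != (n, n) or np.abs(d - d.T).max() > 1e-8:
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(d) != 0.0):
        raise ValueError("distance diagonal must be zero")
    if d.min() < 0:
        raise ValueError("distances must be non-negative")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")
    condensed = squareform((d + d.T) / 2.0, checks=False)
    Z = linkage(condensed, method="average")
    return Dendrogram.from_linkage(Z, list(labels))
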