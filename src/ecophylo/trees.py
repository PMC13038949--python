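"""Rooted phylogenies: Newick I/O, node ages, and clade bipartitions.

The central container is :class:`Phylogeny`, a light array-backed rooted
tree.  Tips get ids ``0 .. n_tips-1`` in the order they appear in the
Newick string; internal nodes get ids ``n_tips .. 2*n_tips-2`` assigned in
post-order, so ids are stable across a write/parse round trip (seeded
permutation tests rely on this).

Newick parsing and writing are delegated to dendropy; this module layers
the validation the comparative analyses need on top (unique tip labels,
branch lengths present and positive, binary topology where required,
ultrametricity within tolerance).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NewickError",
    "NotUltrametricError",
    "PolytomyError",
    "parse_newick",
    "write_newick",
    "node_ages",
    "clade_bipartitions",
]


class NewickError(ValueError):
    """Malformed or invalid Newick input (position reported when known)."""


class NotUltrametricError(ValueError):
    """Tree is not ultrametric within the requested tolerance."""


class PolytomyError(ValueError):
    """A node has more than two children where a binary tree is required."""


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in time units.

    Attributes
    ----------
    parent : int array, length n_nodes; parent id of each node, -1 for root.
    children : list of child-id lists, indexed by node id.
    edge_length : float array; length of the edge above each node (root: 0).
    tip_labels : tip label for id ``i`` (tips are ids ``0..n_tips-1``).
    """

    parent: np.ndarray
    children: list[list[int]]
    edge_length: np.ndarray
    tip_labels: list[str]
    _postorder: np.ndarray | None = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------ basic
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def postorder(self) -> np.ndarray:
        """Node ids in post-order (children before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=np.intp)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.edge_length[node]
        return d

    @property
    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def clade_tips(self, node: int) -> list[int]:
        """Tip ids descending from ``node`` (the node itself if a tip)."""
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(out)

    # ------------------------------------------------------------- validation
    def validate(self, allow_zero_lengths: bool = False) -> None:
        n = self.n_nodes
        if n != len(self.parent) or n != len(self.edge_length):
            raise NewickError("inconsistent node arrays")
        if (self.parent < 0).sum() != 1:
            raise NewickError("tree must have exactly one root")
        if len(set(self.tip_labels)) != self.n_tips:
            dup = sorted({t for t in self.tip_labels if self.tip_labels.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        if any(not lab for lab in self.tip_labels):
            raise NewickError("empty tip label")
        if len(self.postorder()) != n:
            raise NewickError("tree is not connected")
        non_root = np.arange(n) != self.root
        bad = non_root & ~(self.edge_length > 0)
        if not allow_zero_lengths and bad.any():
            raise NewickError(
                f"non-positive branch length above node(s) {np.flatnonzero(bad).tolist()}"
            )

    # ------------------------------------------------------------ construction
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        leaves = [lf for lf in dtree.leaf_node_iter()]
        # tip order = appearance order in the newick (dendropy preserves it)
        tip_labels = []
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise NewickError("tip without a label")
            tip_labels.append(str(lf.taxon.label))
        n_tips = len(tip_labels)
        ids: dict[int, int] = {id(lf): i for i, lf in enumerate(leaves)}
        next_id = n_tips
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                continue
            ids[id(nd)] = next_id
            next_id += 1
        n_nodes = next_id
        parent = np.full(n_nodes, -1, dtype=np.intp)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        edge_length = np.zeros(n_nodes)
        for nd in dtree.postorder_node_iter():
            i = ids[id(nd)]
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                if nd.edge.length is None:
                    raise NewickError(f"missing branch length above node {i}")
                edge_length[i] = float(nd.edge.length)
        for ch in children:
            ch.sort()
        return cls(parent=parent, children=children, edge_length=edge_length,
                   tip_labels=tip_labels)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Requires branch lengths on all non-root edges, unique nonempty tip
    labels, and a single root.  Raises :class:`NewickError` (with the
    parser's position information where available) otherwise.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"newick parse failure: {exc}") from exc
    tree = Phylogeny.from_dendropy(dtree)
    tree.validate()
    return tree


def write_newick(tree: Phylogeny, digits: int = 10) -> str:
    """Serialize to Newick, branch lengths at ``digits`` significant digits."""
    fmt = f"%.{digits}g"
    buf = io.StringIO()

    def emit(node: int) -> None:
        kids = tree.children[node]
        if kids:
            buf.write("(")
            for j, child in enumerate(kids):
                if j:
                    buf.write(",")
                emit(child)
            buf.write(")")
        else:
            buf.write(tree.tip_labels[node])
        if tree.parent[node] >= 0:
            buf.write(":" + fmt % tree.edge_length[node])

    emit(tree.root)
    buf.write(";")
    return buf.getvalue()


def node_ages(tree: Phylogeny, tol: float = 1e-6) -> np.ndarray:
    """Ages (time before present) of every node of an ultrametric tree.

    ``age(node) = height - depth(node)``; tip ages are clamped to exactly 0.
    ``tol`` is the tolerated relative spread of tip depths (chronograms from
    external dating tools carry rounding error).

    Raises
    ------
    NotUltrametricError
        if ``(max tip depth - min tip depth) / height > tol``, naming the
        shallowest and deepest tips.
    """
    depths = tree.depths()
    tip_d = depths[: tree.n_tips]
    height = tip_d.max()
    if height <= 0:
        raise NotUltrametricError("tree has zero height")
    spread = (tip_d.max() - tip_d.min()) / height
    if spread > tol:
        lo = tree.tip_labels[int(np.argmin(tip_d))]
        hi = tree.tip_labels[int(np.argmax(tip_d))]
        raise NotUltrametricError(
            f"tree not ultrametric: relative tip-depth spread {spread:.3g} > {tol:.3g} "
            f"(shallowest tip {lo!r}, deepest tip {hi!r})"
        )
    ages = height - depths
    ages[: tree.n_tips] = 0.0
    return ages


def clade_bipartitions(tree: Phylogeny) -> dict[int, tuple[list[int], list[int]]]:
    """For each internal node of a binary tree, the two child tip sets.

    Returns a map ``node id -> (left tip ids, right tip ids)`` where left
    and right are the node's two children's clades (disjoint, nonempty,
    union = the node's clade).  Polytomies are rejected: resolving them
    silently would change node ages in the age-overlap regression.
    """
    out: dict[int, tuple[list[int], list[int]]] = {}
    for node in range(tree.n_tips, tree.n_nodes):
        kids = tree.children[node]
        if len(kids) != 2:
            raise PolytomyError(
                f"node {node} has {len(kids)} children; binary tree required"
            )
        out[node] = (tree.clade_tips(kids[0]), tree.clade_tips(kids[1]))
    return out
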