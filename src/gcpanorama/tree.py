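"""Rooted phylogenies: parsing, traversal, and Brownian-motion covariance.

The central object is :class:`PhyloTree`, a lightweight rooted tree with
branch lengths, parsed from / written to Newick via dendropy.  The
phylogenetic variance-covariance matrix ``C`` (``C[a, b]`` = shared
root-to-MRCA path length of tips ``a`` and ``b``) is the basis of every
comparative statistic in :mod:`gcpanorama.phylo_comparative`, and the three
classical branch-length transforms (Pagel's lambda, kappa, delta) are
implemented here so that both simulation and estimation share one code path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy
import numpy as np

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "read_newick",
    "parse_newick",
    "write_newick",
    "to_newick",
    "vcv",
    "transform_vcv",
    "transform_tree_kappa",
    "midpoint_root",
]


@dataclass(eq=False)  # identity semantics: nodes are used as dict keys
class PhyloNode:
    """One node of a rooted tree; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    parent: "PhyloNode | None" = None
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """A rooted phylogeny with branch lengths and unique tip labels.

    Tip order (the order used for trait vectors and covariance matrices)
    is the left-to-right order of tips in the underlying Newick string and
    is stable across round trips.
    """

    def __init__(self, root: PhyloNode):
        self.root = root
        labels = [t.name for t in self.tips()]
        if any(l is None or l == "" for l in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[PhyloNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[PhyloNode]:
        out: list[PhyloNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self, include_root: bool = True) -> list[PhyloNode]:
        nodes = [n for n in self.preorder() if not n.is_tip]
        if not include_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def depths(self) -> dict[PhyloNode, float]:
        """Root-to-node path length for every node (root depth 0)."""
        d: dict[PhyloNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                d[node] = d[node.parent] + node.length
        return d

    def max_depth(self) -> float:
        d = self.depths()
        return max(d[t] for t in self.tips())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()
        td = np.array([d[t] for t in self.tips()])
        span = td.max() - td.min()
        return bool(span <= rel_tol * max(td.max(), 1e-300))

    def copy(self) -> "PhyloTree":
        mapping: dict[PhyloNode, PhyloNode] = {}
        for node in self.preorder():
            clone = PhyloNode(name=node.name, length=node.length)
            mapping[node] = clone
            if node.parent is not None:
                mapping[node.parent].add_child(clone)
        return PhyloTree(mapping[self.root])

    def label_internal_nodes(self, prefix: str = "node") -> None:
        """Assign names node0, node1, ... (preorder; root first) where missing."""
        i = 0
        for node in self.preorder():
            if not node.is_tip:
                if not node.name:
                    node.name = f"{prefix}{i}"
                i += 1

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


# -- Newick I/O (dendropy-backed) ------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode: dendropy.Node) -> PhyloNode:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        node = PhyloNode(name=name, length=float(dnode.edge.length or 0.0))
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def parse_newick(newick: str, require_bifurcating_root: bool = True) -> PhyloTree:
    """Parse a Newick string into a rooted :class:`PhyloTree`.

    Internal polytomies are allowed, but a basal trifurcation usually means
    the tree is unrooted, so by default it is rejected with a pointer to
    :func:`midpoint_root`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    if require_bifurcating_root and len(tree.root.children) > 2:
        raise ValueError(
            f"root has {len(tree.root.children)} children; the tree looks "
            "unrooted. Root it first (e.g. gcpanorama.tree.midpoint_root or "
            "outgroup rooting), or pass require_bifurcating_root=False."
        )
    return tree


def read_newick(path, require_bifurcating_root: bool = True) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read(), require_bifurcating_root)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ();:,[]'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PhyloTree, include_internal_labels: bool = True) -> str:
    """Serialize with 12 significant digits so round trips hold to 1e-9."""

    def fmt(node: PhyloNode, is_root: bool) -> str:
        if node.is_tip:
            body = _quote_label(node.name)
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if include_internal_labels and node.name:
                label = _quote_label(node.name)
            body = f"({inner}){label}"
        if is_root:
            return body
        return f"{body}:{node.length:.12g}"

    return fmt(tree.root, True) + ";"


def write_newick(tree: PhyloTree, path, include_internal_labels: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, include_internal_labels) + "\n")


# -- covariance construction and transforms --------------------------------

def vcv(tree: PhyloTree, tip_order: list[str] | None = None) -> np.ndarray:
    """Brownian-motion variance-covariance matrix of the tips.

    ``C[a, b]`` is the root-to-MRCA path length of tips ``a`` and ``b``;
    the diagonal holds root-to-tip depths.  Positive semidefinite by
    construction.
    """
    tips = tree.tips()
    labels = [t.name for t in tips]
    index = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    depths = tree.depths()
    C = np.zeros((n, n))
    # For every internal node u, tip pairs whose MRCA is u get C = depth(u):
    # cross-pairs between distinct child subtrees of u.
    subtree_tips: dict[PhyloNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            subtree_tips[node] = np.array([index[node]])
            continue
        child_sets = [subtree_tips[c] for c in node.children]
        for i, a in enumerate(child_sets):
            for b in child_sets[i + 1:]:
                C[np.ix_(a, b)] = depths[node]
                C[np.ix_(b, a)] = depths[node]
        subtree_tips[node] = np.concatenate(child_sets)
    for t in tips:
        C[index[t], index[t]] = depths[t]
    if tip_order is not None:
        perm = [labels.index(l) for l in tip_order]
        C = C[np.ix_(perm, perm)]
    return C


def transform_tree_kappa(tree: PhyloTree, kappa: float) -> PhyloTree:
    """Raise every branch length to the power ``kappa`` (0**k kept at 0)."""
    if kappa < 0:
        raise ValueError("kappa must be positive")
    out = tree.copy()
    for node in out.preorder():
        if node is not out.root and node.length > 0:
            node.length = node.length ** kappa
    return out


def transform_vcv(C: np.ndarray, which: str, param: float) -> np.ndarray:
    """Apply a branch-length transform directly to a covariance matrix.

    lambda: off-diagonal entries multiplied by ``param`` (param in [0, 1]).
    delta:  every entry (a node depth) raised to the power ``param``.
    kappa has no exact vcv-level form; use :func:`transform_tree_kappa` and
    rebuild the matrix with :func:`vcv`.
    """
    if which == "lambda":
        lam = float(param)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        out = C * lam
        np.fill_diagonal(out, np.diag(C))
        return out
    if which == "delta":
        delta = float(param)
        if delta <= 0:
            raise ValueError("delta must be positive")
        return np.power(C, delta)
    raise ValueError(f"unknown vcv transform {which!r} (use lambda or delta)")


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Reroot at the midpoint of the longest tip-to-tip path.

    Explicit utility for trees arriving unrooted; nothing in the package
    reroots silently.
    """
    dtree = dendropy.Tree.get(
        data=to_newick(tree, include_internal_labels=False),
        schema="newick",
        preserve_underscores=True,
    )
    dtree.reroot_at_midpoint(update_bipartitions=False)
    out = io.StringIO()
    dtree.write(file=out, schema="newick", suppress_rooting=True,
                unquoted_underscores=True)
    return parse_newick(out.getvalue(), require_bifurcating_root=False)
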