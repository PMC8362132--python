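"""Rooted phylogeny with branch lengths, Newick I/O and the Brownian covariance.

Wraps :mod:`dendropy` for parsing/serialising and keeps flat integer-indexed
arrays for the numerical work done downstream (covariance, simulation,
pruning-based statistics).  Tips are indexed ``0..n_tips-1``; internal nodes
follow in postorder, so ``node_ids[-1]`` is always the root.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "read_newick",
    "write_newick",
    "bm_covariance",
    "simulate_bm",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or missing branch lengths."""


class Phylogeny:
    """Rooted tree with branch lengths in time units.

    Parameters
    ----------
    dtree:
        A rooted :class:`dendropy.Tree`.  Every non-root edge must carry a
        branch length; a missing root edge length is treated as 0.

    Attributes
    ----------
    n_tips : int
    n_nodes : int
    tip_labels : list of str
        Label of tip ``i`` for ``i < n_tips``.
    parent : ndarray of int
        Parent node id per node; −1 for the root.
    edge_length : ndarray of float
        Length of the edge above each node; 0 for the root unless given.
    children : list of list of int
    """

    def __init__(self, dtree: dendropy.Tree):
        if dtree.seed_node is None:
            raise NewickError("empty tree")
        leaves = [nd for nd in dtree.leaf_node_iter()]
        n_tips = len(leaves)
        internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
        ids: dict[dendropy.Node, int] = {}
        for i, nd in enumerate(leaves):
            ids[nd] = i
        for j, nd in enumerate(internals):
            ids[nd] = n_tips + j

        n_nodes = n_tips + len(internals)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        length = np.zeros(n_nodes, dtype=np.float64)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        labels: list[str] = []
        for nd in leaves:
            lab = None
            if nd.taxon is not None and nd.taxon.label is not None:
                lab = nd.taxon.label
            elif nd.label is not None:
                lab = nd.label
            if lab is None:
                raise NewickError("tip without a label")
            labels.append(lab.replace(" ", "_"))
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")

        root = dtree.seed_node
        for nd, i in ids.items():
            if nd is not root:
                parent[i] = ids[nd.parent_node]
                if nd.edge.length is None:
                    raise NewickError(
                        "missing branch length on edge above node "
                        f"{_describe_node(nd)}"
                    )
                length[i] = float(nd.edge.length)
                children[ids[nd.parent_node]].append(i)
            else:
                length[i] = float(nd.edge.length) if nd.edge.length is not None else 0.0

        self.n_tips = n_tips
        self.n_nodes = n_nodes
        self.tip_labels = labels
        self.parent = parent
        self.edge_length = length
        self.children = children
        self.root = ids[root]
        self._tip_index = {lab: i for i, lab in enumerate(labels)}

    # ------------------------------------------------------------------ io

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    def to_newick(self) -> str:
        """Serialise preserving branch lengths to ≥ 17 significant digits."""
        parts: list[str] = [""] * self.n_nodes
        for i in self.postorder():
            if self.children[i]:
                inner = ",".join(parts[c] for c in self.children[i])
                parts[i] = f"({inner})"
            else:
                parts[i] = self.tip_labels[i]
            if i != self.root:
                parts[i] += f":{self.edge_length[i]:.17g}"
            else:
                parts[i] += f":{self.edge_length[i]:.17g};"
        return parts[self.root]

    # --------------------------------------------------------- traversals

    def postorder(self) -> list[int]:
        """Node ids, children before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            # reversed keeps child order stable between runs
            stack.extend(reversed(self.children[nd]))
        return order

    def node_depths(self) -> np.ndarray:
        """Distance to every node from the top of the root edge.

        The root edge (stem) counts as shared history: including it makes
        pruning commute exactly with covariance sub-matrix selection, and
        it only ever adds a constant to the BM covariance.
        """
        depth = np.zeros(self.n_nodes)
        depth[self.root] = self.edge_length[self.root]
        for i in self.preorder():
            if i != self.root:
                depth[i] = depth[self.parent[i]] + self.edge_length[i]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_tips]

    def subtree_tips(self, node: int) -> frozenset[int]:
        """Tip ids descending from (and including, if a tip) ``node``."""
        tips: list[int] = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd < self.n_tips:
                tips.append(nd)
            stack.extend(self.children[nd])
        return frozenset(tips)

    def n_subtree_tips(self) -> np.ndarray:
        """Number of descendant tips per node."""
        count = np.zeros(self.n_nodes, dtype=np.int64)
        for i in self.postorder():
            if i < self.n_tips:
                count[i] = 1
            else:
                count[i] = sum(count[c] for c in self.children[i])
        return count

    def mrca(self, tip_ids: Iterable[int]) -> int:
        """Most recent common ancestor of a set of tips."""
        ids = list(tip_ids)
        if not ids:
            raise ValueError("mrca of empty set")
        # ancestor chains
        chain = set()
        nd = ids[0]
        while nd != -1:
            chain.add(nd)
            nd = self.parent[nd]
        best = None
        for t in ids[1:]:
            nd = t
            while nd not in chain:
                nd = self.parent[nd]
            sub = set()
            m = nd
            while m != -1:
                sub.add(m)
                m = self.parent[m]
            chain &= sub
        depth = self.node_depths()
        best = max(chain, key=lambda x: depth[x])
        return best

    def tip_ids(self, labels: Sequence[str]) -> list[int]:
        missing = [lab for lab in labels if lab not in self._tip_index]
        if missing:
            raise KeyError(f"labels not in tree: {missing[:5]}")
        return [self._tip_index[lab] for lab in labels]

    def terminal_branch_length(self, label: str) -> float:
        return float(self.edge_length[self._tip_index[label]])

    # ------------------------------------------------------------ pruning

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Subtree spanned by ``labels``, measured from the original root.

        Pass-through (unifurcating) nodes are collapsed by summing branch
        lengths, so root-to-tip and shared-path distances are preserved.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)[:5]}")
        if not keep:
            raise ValueError("cannot prune to empty tip set")
        dtree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        taxa = [t for t in dtree.taxon_namespace if t.label in keep]
        dtree.retain_taxa(taxa)
        # retain_taxa suppresses internal unifurcations; a chain may remain
        # at the root — collapse it onto the root edge to keep depths.
        while (
            dtree.seed_node.num_child_nodes() == 1
            and not dtree.seed_node.is_leaf()
        ):
            child = dtree.seed_node.child_nodes()[0]
            extra = child.edge.length or 0.0
            base = dtree.seed_node.edge.length or 0.0
            dtree.seed_node = child
            child.parent_node = None
            child.edge.length = base + extra
        return Phylogeny(dtree)


def _describe_node(nd: dendropy.Node) -> str:
    if nd.is_leaf():
        lab = nd.taxon.label if nd.taxon else nd.label
        return f"tip '{lab}'"
    tips = [lf.taxon.label for lf in nd.leaf_iter() if lf.taxon]
    return f"clade of {{{', '.join(sorted(tips)[:3])}...}}"


def read_newick(path: str) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    with open(path) as fh:
        return Phylogeny.from_newick(fh.read())


def write_newick(tree: Phylogeny, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def bm_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion tip covariance: shared path length from the root.

    ``C[i, j]`` is the depth of the MRCA of tips *i* and *j*; the diagonal
    holds root-to-tip distances.  Symmetric and positive semi-definite.
    """
    if np.any(tree.edge_length < 0):
        bad = int(np.argmin(tree.edge_length))
        raise ValueError(f"negative branch length on edge above node {bad}")
    n = tree.n_tips
    depth = tree.node_depths()
    C = np.zeros((n, n))
    for nd in tree.postorder():
        if nd < n:
            continue
        kids = tree.children[nd]
        sets = [np.fromiter(tree.subtree_tips(c), dtype=np.int64) for c in kids]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                C[np.ix_(sets[a], sets[b])] = depth[nd]
                C[np.ix_(sets[b], sets[a])] = depth[nd]
    C[np.diag_indices(n)] = depth[:n]
    return C


def simulate_bm(
    tree: Phylogeny,
    rate: float,
    n_sims: int,
    rng: np.random.Generator,
    root_value: float = 0.0,
) -> np.ndarray:
    """Brownian-motion realisations at the tips, shape ``(n_tips, n_sims)``.

    Equivalent to sampling MVN(root_value, rate·C) but O(nodes × sims) via
    independent Gaussian increments along each edge.
    """
    if rate < 0:
        raise ValueError("BM rate must be non-negative")
    x = np.empty((tree.n_nodes, n_sims))
    x[tree.root] = root_value
    sd = np.sqrt(rate * np.maximum(tree.edge_length, 0.0))
    for nd in tree.preorder():
        if nd == tree.root:
            continue
        x[nd] = x[tree.parent[nd]] + rng.standard_normal(n_sims) * sd[nd]
    return x[: tree.n_tips]
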