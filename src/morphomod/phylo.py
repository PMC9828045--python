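"""Shared phylogenetic machinery.

Species covariance matrices under Brownian motion (BM), single-optimum
Ornstein-Uhlenbeck (OU) and early-burst (EB) models, Felsenstein's
independent contrasts, and generalized-least-squares root estimates.

Branch lengths are in absolute time (Myr for the datasets this package
targets); a covariance under unit rate is returned and the evolutionary
rate enters through the trait covariance downstream.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np


@dataclass
class SpeciesCovariance:
    """N x N expected trait covariance among species under a named model."""

    matrix: np.ndarray
    model: str  # "BM", "OU", "EB"
    parameter: float  # alpha for OU, r for EB, 0.0 for BM
    tip_labels: list[str]


class Phylogeny:
    """A rooted tree with branch lengths, backed by dendropy.

    Exposes the quantities the analysis needs: tip labels in a stable
    order, tree height, pairwise shared path lengths (MRCA depths) and
    patristic distances, pruning, and Newick round-tripping.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for e in tree.preorder_edge_iter():
            if e.head_node is tree.seed_node:
                continue
            if e.length is None:
                raise ValueError("tree has missing branch lengths")
            if e.length < 0:
                raise ValueError(f"negative branch length {e.length}")
        self.tip_labels: list[str] = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("duplicate tip labels")
        if len(self.tip_labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        self._depths = {}
        for node in tree.preorder_node_iter():
            parent_depth = 0.0 if node.parent_node is None else self._depths[node.parent_node]
            self._depths[node] = parent_depth + (node.edge.length or 0.0)
        self.height: float = max(self._depths[l] for l in tree.leaf_node_iter())
        if self.height <= 0:
            raise ValueError("tree height must be positive")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())

    # -- basic queries -------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = [self._depths[l] for l in self._tree.leaf_node_iter()]
        return (max(depths) - min(depths)) <= rel_tol * self.height

    def tip_depths(self) -> np.ndarray:
        return np.array([self._depths[l] for l in self._tree.leaf_node_iter()])

    def prune(self, tips: Sequence[str]) -> "Phylogeny":
        missing = sorted(set(tips) - set(self.tip_labels))
        if missing:
            raise ValueError(f"tips not in tree: {missing}")
        tree = self._tree.clone(depth=1)
        keep = [t for t in tree.taxon_namespace if t.label in set(tips)]
        tree.retain_taxa(keep)
        tree.purge_taxon_namespace()
        return Phylogeny(tree)

    def check_tips(self, labels: Sequence[str]) -> None:
        tree_only = sorted(set(self.tip_labels) - set(labels))
        data_only = sorted(set(labels) - set(self.tip_labels))
        if tree_only or data_only:
            raise ValueError(
                f"tip/specimen mismatch: in tree only {tree_only}, in data only {data_only}"
            )

    # -- pairwise time structure --------------------------------------------

    def shared_times(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Matrix of root-to-MRCA path lengths t_ij for every tip pair.

        The diagonal holds root-to-tip depths.  This is the BM covariance
        under unit rate.
        """
        order = list(order) if order is not None else self.tip_labels
        leaves = {l.taxon.label: l for l in self._tree.leaf_node_iter()}
        n = len(order)
        # MRCA depth via bitmask ancestry walk; fine for the tree sizes used here
        anc = {}
        for lab in order:
            node = leaves[lab]
            chain = []
            while node is not None:
                chain.append(node)
                node = node.parent_node
            anc[lab] = chain
        out = np.zeros((n, n))
        for i, a in enumerate(order):
            seta = {id(x): self._depths[x] for x in anc[a]}
            out[i, i] = self._depths[leaves[a]]
            for j in range(i + 1, n):
                b = order[j]
                for node in anc[b]:
                    if id(node) in seta:
                        out[i, j] = out[j, i] = self._depths[node]
                        break
        return out

    def patristic_distances(self, order: Sequence[str] | None = None) -> np.ndarray:
        t = self.shared_times(order)
        d = np.diag(t)
        return d[:, None] + d[None, :] - 2 * t

    def rescale(self, height: float) -> "Phylogeny":
        """Return a copy with branch lengths scaled so the height equals ``height``."""
        tree = self._tree.clone(depth=1)
        f = height / self.height
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= f
        return Phylogeny(tree)

    # -- traversal for contrasts --------------------------------------------

    def _resolved_postorder(self):
        """Postorder nodes of a copy with polytomies resolved by zero-length branches."""
        tree = self._tree.clone(depth=1)
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
        return tree


def species_covariance(tree: Phylogeny, model: str = "BM", parameter: float = 0.0,
                       order: Sequence[str] | None = None) -> SpeciesCovariance:
    """Unit-rate expected trait covariance among species under BM, OU or EB.

    BM: ``C_ij = t_ij`` (shared path length).  OU with a fixed root at the
    optimum: ``C_ij = exp(-alpha d_ij) (1 - exp(-2 alpha t_ij)) / (2 alpha)``
    with ``d_ij`` the patristic distance; requires an ultrametric tree.
    EB: ``C_ij = (exp(r t_ij) - 1)/r`` with the BM limit taken analytically
    as ``r -> 0``.
    """
    order = list(order) if order is not None else tree.tip_labels
    t = tree.shared_times(order)
    model = model.upper()
    if model == "BM":
        return SpeciesCovariance(t, "BM", 0.0, order)
    if model == "OU":
        alpha = float(parameter)
        if alpha < 0:
            raise ValueError("OU requires alpha >= 0")
        if not tree.is_ultrametric():
            raise ValueError("OU covariance requires an ultrametric tree")
        if alpha == 0:
            return SpeciesCovariance(t, "OU", 0.0, order)
        d = tree.patristic_distances(order)
        c = np.exp(-alpha * d) * (1.0 - np.exp(-2.0 * alpha * t)) / (2.0 * alpha)
        return SpeciesCovariance(c, "OU", alpha, order)
    if model == "EB":
        r = float(parameter)
        if abs(r) * tree.height > 50:
            raise ValueError("|r| * height must be <= 50")
        if abs(r) < 1e-8:
            return SpeciesCovariance(t, "EB", r, order)
        c = (np.exp(r * t) - 1.0) / r
        return SpeciesCovariance(c, "EB", r, order)
    raise ValueError(f"unknown model {model!r}")


def independent_contrasts(tree: Phylogeny, X: np.ndarray, order: Sequence[str] | None = None) -> np.ndarray:
    """Felsenstein's standardized independent contrasts of an N x q trait matrix.

    Rows of ``X`` follow ``order`` (default: the tree's tip order).  Each of
    the N-1 contrasts is divided by its expected standard deviation; branch
    lengths at internal nodes are extended by the usual ``v1 v2/(v1+v2)``
    recursion.  Polytomies are resolved arbitrarily with zero-length branches.
    """
    order = list(order) if order is not None else tree.tip_labels
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(order):
        raise ValueError("X rows must match tip count")
    pos = {lab: i for i, lab in enumerate(order)}
    work = tree._resolved_postorder()

    values: dict = {}
    lengths: dict = {}
    contrasts = []
    for node in work.postorder_node_iter():
        if node.is_leaf():
            values[node] = X[pos[node.taxon.label]].copy()
            lengths[node] = node.edge.length or 0.0
        else:
            children = node.child_nodes()
            assert len(children) == 2
            a, b = children
            v1, v2 = lengths[a], lengths[b]
            if v1 + v2 <= 0:
                raise ValueError("zero-length sibling pair: contrast variance is zero")
            contrasts.append((values[a] - values[b]) / np.sqrt(v1 + v2))
            values[node] = (v2 * values[a] + v1 * values[b]) / (v1 + v2)
            lengths[node] = (node.edge.length or 0.0) + v1 * v2 / (v1 + v2)
    return np.array(contrasts)


def gls_root(tree: Phylogeny, X: np.ndarray, order: Sequence[str] | None = None,
             cov: np.ndarray | None = None) -> np.ndarray:
    """GLS estimate of the root state: ``(1' C^-1 1)^-1 1' C^-1 X`` under BM."""
    order = list(order) if order is not None else tree.tip_labels
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(order):
        raise ValueError("X rows must match tip count")
    C = cov if cov is not None else species_covariance(tree, "BM", order=order).matrix
    try:
        Ci1 = np.linalg.solve(C, np.ones(len(order)))
    except np.linalg.LinAlgError as e:
        raise ValueError("singular species covariance") from e
    return (Ci1 @ X) / Ci1.sum()
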