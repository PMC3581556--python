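"""Phylogenetic diversity of cell assemblages: Faith's PD, PSV, PSC.

Faith's PD is the branch-length sum of the minimal subtree connecting an
assemblage (root-inclusive by default, so single-species PD is the tip's
root-to-tip distance). PSV and PSC are computed from the phylogenetic
correlation matrix C, where c_ij is the root-to-MRCA shared path length
of tips i and j scaled by the geometric mean of their depths — for an
ultrametric tree this is shared depth over total depth. PSV is one minus
the mean off-diagonal correlation (high when members are spread across
the whole tree); PSC is one minus the mean of each member's largest
correlation with another member (high when members are not clustered at
the tips).
"""

from __future__ import annotations

import math
from typing import Iterable

import dendropy
import numpy as np


class UnknownSpeciesError(KeyError):
    """An assemblage member is not a tip of the phylogeny."""


class Phylogeny:
    """A rooted tree with branch lengths, preprocessed for fast indexing.

    Wraps a :class:`dendropy.Tree`; tip labels are the species ids used
    throughout the package and must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        order = np.argsort(labels)
        self.tips = [labels[i] for i in order]
        self._tip_index = {sp: j for j, sp in enumerate(self.tips)}
        leaves = [leaves[i] for i in order]

        # edge table: every node except the (lengthless) root contributes
        # the edge to its parent; record per-edge tip-descendant sets
        nodes = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        self.edge_lengths = np.array(
            [nd.edge.length if nd.edge.length is not None else 0.0 for nd in nodes]
        )
        if (self.edge_lengths < 0).any():
            raise ValueError("branch lengths must be nonnegative")
        S = len(self.tips)
        self.edge_tips = np.zeros((len(nodes), S), dtype=bool)
        node_pos = {id(nd): k for k, nd in enumerate(nodes)}
        for lf in leaves:
            j = self._tip_index[lf.taxon.label]
            nd = lf
            while nd.parent_node is not None:
                self.edge_tips[node_pos[id(nd)], j] = True
                nd = nd.parent_node
        self.tip_depths = self.edge_tips.T @ self.edge_lengths

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def total_branch_length(self) -> float:
        return float(self.edge_lengths.sum())

    def tip_indices(self, taxa: Iterable[str]) -> np.ndarray:
        idx = []
        for sp in taxa:
            if sp not in self._tip_index:
                raise UnknownSpeciesError(f"species {sp!r} is not a tip of the phylogeny")
            idx.append(self._tip_index[sp])
        return np.asarray(sorted(idx), dtype=np.int64)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return float(self.tip_depths.max() - self.tip_depths.min()) <= tol


def faith_pd(tree: Phylogeny, taxa: Iterable[str], root_inclusive: bool = True) -> float:
    """Branch-length sum of the minimal subtree spanning ``taxa``.

    Root-inclusive (default): the subtree always contains the tree root,
    so PD of a single species equals its root-to-tip distance. With
    ``root_inclusive=False`` edges above the assemblage MRCA are dropped
    (an edge counts only if it separates assemblage members).
    """
    idx = tree.tip_indices(taxa)
    if len(idx) == 0:
        return math.nan
    on_path = tree.edge_tips[:, idx]
    counts = on_path.sum(axis=1)
    if root_inclusive:
        keep = counts > 0
    else:
        keep = (counts > 0) & (counts < len(idx))
    return float(tree.edge_lengths[keep].sum())


def phylo_correlation(tree: Phylogeny) -> np.ndarray:
    """Tip correlation matrix C: shared path length standardized by depths.

    c_ij = (root-to-MRCA shared branch length of i, j) / sqrt(d_i * d_j).
    Symmetric, unit diagonal, entries in [0, 1]. A zero-depth tip makes
    the standardization undefined and raises.
    """
    d = tree.tip_depths
    if (d <= 0).any():
        bad = [tree.tips[j] for j in np.flatnonzero(d <= 0)]
        raise ValueError(f"zero-depth tips make correlations undefined: {bad}")
    E = tree.edge_tips
    shared = (E * tree.edge_lengths[:, None]).T @ E  # vcv: shared path lengths
    C = shared / np.sqrt(np.outer(d, d))
    np.fill_diagonal(C, 1.0)
    return C


def _submatrix(C: np.ndarray, tree: Phylogeny, taxa: Iterable[str]) -> np.ndarray:
    idx = tree.tip_indices(taxa)
    return C[np.ix_(idx, idx)]


def psv(C: np.ndarray, tree: Phylogeny, taxa: Iterable[str]) -> float:
    """Phylogenetic species variability: 1 - mean off-diagonal correlation."""
    Cs = _submatrix(C, tree, taxa)
    n = Cs.shape[0]
    if n < 2:
        return math.nan
    return float((n * np.trace(Cs) - Cs.sum()) / (n * (n - 1)))


def psc(C: np.ndarray, tree: Phylogeny, taxa: Iterable[str]) -> float:
    """Phylogenetic species clustering: 1 - mean nearest-relative correlation."""
    Cs = _submatrix(C, tree, taxa).copy()
    n = Cs.shape[0]
    if n < 2:
        return math.nan
    np.fill_diagonal(Cs, -np.inf)
    return float(1.0 - Cs.max(axis=1).mean())
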