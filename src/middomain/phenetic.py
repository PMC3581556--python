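"""Phenetic (morphospace) diversity of cell assemblages.

Species sit in a K-dimensional log-trait space (K = 7 craniometric and
external measures in the motivating system). Three assemblage summaries
are computed on the Euclidean geometry of that space:

* morphological volume — the product of per-trait ranges (an axis-
  aligned box hypervolume);
* MST-SD — the sample standard deviation of the edge lengths of a
  minimum spanning tree over the assemblage (variability of spacing);
* mean NND — the mean distance from each species to its nearest
  neighbor (packing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import csgraph_from_dense, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform


class UnknownSpeciesError(KeyError):
    pass


@dataclass
class TraitMatrix:
    """Species x K matrix of (already log-transformed) trait values."""

    frame: pd.DataFrame  # index = species ids, columns = trait names

    def __post_init__(self):
        if not np.isfinite(self.frame.to_numpy(dtype=float)).all():
            raise ValueError("trait values must be finite")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate species ids in trait matrix")
        if self.frame.shape[1] < 1:
            raise ValueError("at least one trait column required")

    @property
    def species(self) -> list:
        return sorted(self.frame.index)

    @property
    def n_traits(self) -> int:
        return self.frame.shape[1]

    def submatrix(self, taxa: Iterable[str]) -> np.ndarray:
        taxa = sorted(taxa)
        missing = [sp for sp in taxa if sp not in self.frame.index]
        if missing:
            raise UnknownSpeciesError(f"species missing from trait matrix: {missing}")
        return self.frame.loc[taxa].to_numpy(dtype=float)


def morphological_volume(taxa: Iterable[str], traits: TraitMatrix) -> float:
    """Product over traits of the assemblage's trait range (box volume).

    Undefined (NaN) below two species — a single point spans no volume.
    Zero whenever the assemblage is flat in any one trait.
    """
    X = traits.submatrix(taxa)
    if X.shape[0] < 2:
        return math.nan
    return float(np.prod(X.max(axis=0) - X.min(axis=0)))


def mst_edge_lengths(X: np.ndarray) -> np.ndarray:
    """Edge lengths of a Euclidean minimum spanning tree over point rows.

    Ties between equal-weight edges are broken deterministically by the
    implementation's fixed edge ordering (lexicographic in row index),
    so repeated calls agree; the edge-length multiset is unique anyway
    whenever pairwise distances are distinct.
    """
    return mst_edges_from_dist(squareform(pdist(X)))


def mst_edges_from_dist(D: np.ndarray) -> np.ndarray:
    """MST edge lengths from a precomputed symmetric distance matrix."""
    n = D.shape[0]
    # inf marks "no edge" so that zero-length edges (coincident points)
    # survive the sparse conversion instead of being dropped
    graph = csgraph_from_dense(D, null_value=np.inf)
    mst = minimum_spanning_tree(graph)
    edges = np.sort(np.asarray(mst.data, dtype=float))
    if len(edges) < n - 1:  # zero-weight edges stored implicitly
        edges = np.concatenate([np.zeros(n - 1 - len(edges)), edges])
    return edges


def mst_sd(taxa: Iterable[str], traits: TraitMatrix) -> float:
    """Sample SD (n-1 denominator) of MST edge lengths; NaN below 3 species."""
    X = traits.submatrix(taxa)
    if X.shape[0] < 3:
        return math.nan
    edges = mst_edge_lengths(X)
    return float(np.std(edges, ddof=1))


def mean_nnd(taxa: Iterable[str], traits: TraitMatrix) -> float:
    """Mean nearest-neighbor Euclidean distance; NaN below 2 species."""
    X = traits.submatrix(taxa)
    if X.shape[0] < 2:
        return math.nan
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean())
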