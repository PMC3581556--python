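"""Per-cell biodiversity metric tables.

Ten indices are computed for every domain cell from its species list:

=====================  =============================================
column                 definition (NaN where undefined)
=====================  =============================================
richness               number of species (never NaN)
pd                     Faith's phylogenetic diversity (NaN at 0 spp)
psv                    phylogenetic species variability (NaN < 2 spp)
psc                    phylogenetic species clustering (NaN < 2 spp)
functional_richness    guilds represented (NaN at 0 spp)
shannon_fd             Shannon diversity of guild counts (NaN at 0)
camargo_evenness       Camargo evenness of guild counts (NaN at 0)
morph_volume           product of trait ranges (NaN < 2 spp)
mst_sd                 SD of morphospace MST edge lengths (NaN < 3)
mean_nnd               mean nearest-neighbor trait distance (NaN < 2)
=====================  =============================================

A :class:`MetricContext` pre-aligns the phylogeny, guild table and trait
matrix to a fixed species order so that ensembles of randomized presence
matrices (which share that order) are scored without re-resolving
species, using matrix formulations of the same definitions exposed by
the scalar operations in :mod:`middomain.phylo`,
:mod:`middomain.functional` and :mod:`middomain.phenetic`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial.distance import pdist, squareform

from . import functional, phenetic, phylo
from .grid import PresenceMatrix

METRIC_COLUMNS = (
    "richness",
    "pd",
    "psv",
    "psc",
    "functional_richness",
    "shannon_fd",
    "camargo_evenness",
    "morph_volume",
    "mst_sd",
    "mean_nnd",
)


@dataclass(frozen=True)
class MetricConfig:
    """Conventions for edge cases (defaults mirror the package's choices)."""

    pd_root_inclusive: bool = True
    pd_single_species_missing: bool = False
    camargo_all_guilds: bool = False


class MetricContext:
    """Phylogeny / guild / trait structures aligned to one species order."""

    def __init__(
        self,
        species: Sequence[str],
        tree: phylo.Phylogeny,
        guilds: functional.GuildTable,
        traits: phenetic.TraitMatrix,
        config: MetricConfig = MetricConfig(),
    ):
        self.species = list(species)
        self.config = config
        missing = sorted(
            set(sp for sp in self.species if sp not in tree._tip_index)
            | set(sp for sp in self.species if sp not in guilds.assignments)
            | set(sp for sp in self.species if sp not in traits.frame.index)
        )
        if missing:
            raise KeyError(
                f"species unresolvable in tree, guild table or trait matrix: {missing}"
            )
        self.tree = tree
        # re-order tree structures into this context's species order
        col_of = np.array([tree._tip_index[sp] for sp in self.species], dtype=np.int64)
        self.edge_tips = tree.edge_tips[:, col_of]
        self.edge_lengths = tree.edge_lengths
        C_full = phylo.phylo_correlation(tree)
        self.C = C_full[np.ix_(col_of, col_of)]
        self.guild_indicator = guilds.indicator(self.species)
        self.trait_values = traits.frame.loc[self.species].to_numpy(dtype=float)
        self.trait_dist = squareform(pdist(self.trait_values))


@njit(cache=True)
def _pairwise_cell_stats(P, C, D):  # pragma: no cover - exercised via compute_metrics
    """Per-cell PSC, mean NND and MST-SD in one pass.

    P: (cells, S) presence; C: (S, S) phylogenetic correlations;
    D: (S, S) trait distances. The MST uses Prim's algorithm on the
    dense assemblage submatrix — same edge-length multiset as any MST
    when distances are distinct.
    """
    n_cells, S = P.shape
    psc = np.full(n_cells, np.nan)
    nnd = np.full(n_cells, np.nan)
    mst = np.full(n_cells, np.nan)
    idx = np.empty(S, np.int64)
    for c in range(n_cells):
        m = 0
        for s in range(S):
            if P[c, s]:
                idx[m] = s
                m += 1
        if m < 2:
            continue
        acc_c = 0.0
        acc_d = 0.0
        for a in range(m):
            best_c = -1e300
            best_d = 1e300
            ia = idx[a]
            for b in range(m):
                if a == b:
                    continue
                ib = idx[b]
                if C[ia, ib] > best_c:
                    best_c = C[ia, ib]
                if D[ia, ib] < best_d:
                    best_d = D[ia, ib]
            acc_c += best_c
            acc_d += best_d
        psc[c] = 1.0 - acc_c / m
        nnd[c] = acc_d / m
        if m >= 3:
            in_tree = np.zeros(m, np.bool_)
            dmin = np.empty(m)
            in_tree[0] = True
            for b in range(1, m):
                dmin[b] = D[idx[0], idx[b]]
            edges = np.empty(m - 1)
            for e in range(m - 1):
                best = -1
                bd = 1e300
                for b in range(1, m):
                    if not in_tree[b] and dmin[b] < bd:
                        bd = dmin[b]
                        best = b
                edges[e] = bd
                in_tree[best] = True
                for b in range(1, m):
                    if not in_tree[b] and D[idx[best], idx[b]] < dmin[b]:
                        dmin[b] = D[idx[best], idx[b]]
            mu = edges.mean()
            var = 0.0
            for e in range(m - 1):
                var += (edges[e] - mu) ** 2
            mst[c] = np.sqrt(var / (m - 2))
    return psc, nnd, mst


def compute_metrics(
    pm: PresenceMatrix,
    tree: phylo.Phylogeny | None = None,
    guilds: functional.GuildTable | None = None,
    traits: phenetic.TraitMatrix | None = None,
    context: MetricContext | None = None,
    config: MetricConfig = MetricConfig(),
) -> pd.DataFrame:
    """All ten metrics for every cell of a presence matrix.

    Pass either a prebuilt ``context`` (whose species order must match
    ``pm.species``) or the raw ``tree`` / ``guilds`` / ``traits``.
    Returns a DataFrame indexed by cell label.
    """
    if context is None:
        context = MetricContext(pm.species, tree, guilds, traits, config)
    elif context.species != pm.species:
        raise ValueError("context species order does not match the presence matrix")
    cfg = context.config

    P = pm.values
    n_cells = P.shape[0]
    n = P.sum(axis=1).astype(float)
    out = {"richness": n.astype(np.int64)}

    Pf = P.astype(float)

    # Faith's PD: an edge contributes iff it has an assemblage descendant
    desc = Pf @ context.edge_tips.T.astype(float)  # cells x edges tip counts
    if cfg.pd_root_inclusive:
        keep = desc > 0
    else:
        keep = (desc > 0) & (desc < n[:, None])
    pd_vals = keep.astype(float) @ context.edge_lengths
    pd_vals[n == 0] = np.nan
    if cfg.pd_single_species_missing:
        pd_vals[n == 1] = np.nan
    out["pd"] = pd_vals

    # PSV: (n*tr(Cs) - sum(Cs)) / (n(n-1)); diagonal of C is exactly 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sub_sum = ((Pf @ context.C) * Pf).sum(axis=1)
        psv_vals = (n * n - sub_sum) / (n * (n - 1))
    psv_vals[n < 2] = np.nan
    out["psv"] = psv_vals

    # PSC, mean NND and MST-SD share one compiled per-cell pass
    psc_vals, nnd_vals, mst_vals = _pairwise_cell_stats(
        np.ascontiguousarray(P), context.C, context.trait_dist
    )
    out["psc"] = psc_vals

    # functional indices from per-cell guild counts
    counts = Pf @ context.guild_indicator.astype(float)  # cells x G
    present = counts > 0
    g_present = present.sum(axis=1).astype(float)
    fr = g_present.copy()
    fr[n == 0] = np.nan
    out["functional_richness"] = fr
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n[:, None]
        logp = np.where(present, np.log(np.where(present, p, 1.0)), 0.0)
        sh = -(np.where(present, p, 0.0) * logp).sum(axis=1)
    sh[n == 0] = np.nan
    out["shannon_fd"] = sh
    # Camargo: pairwise |p_g - p_h| over present guilds; absent guilds have
    # p = 0, so the present-pair sum is the all-pair sum minus the count of
    # absent guilds (each absent guild pairs with total probability 1)
    G_total = counts.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        all_pairs = np.abs(p[:, :, None] - p[:, None, :]).sum(axis=(1, 2)) / 2.0
        if cfg.camargo_all_guilds:
            cam = 1.0 - all_pairs / G_total
        else:
            present_pairs = all_pairs - (G_total - g_present)
            cam = 1.0 - present_pairs / g_present
    cam[n == 0] = np.nan
    out["camargo_evenness"] = cam

    # morphospace box volume from per-trait masked ranges
    X = context.trait_values
    hi = np.where(P[:, :, None], X[None, :, :], -np.inf).max(axis=1)
    lo = np.where(P[:, :, None], X[None, :, :], np.inf).min(axis=1)
    with np.errstate(invalid="ignore"):
        vol = np.prod(hi - lo, axis=1)
    vol[n < 2] = np.nan
    out["morph_volume"] = vol

    out["mst_sd"] = mst_vals
    out["mean_nnd"] = nnd_vals

    return pd.DataFrame(out, index=pd.Index(pm.domain.cell_labels(), name="cell"))


def ensemble_metric_tables(
    matrices: Iterable[PresenceMatrix],
    context: MetricContext,
) -> list[pd.DataFrame]:
    """Metric table for every matrix of a randomization ensemble."""
    return [compute_metrics(pm, context=context) for pm in matrices]


def ensemble_mean_table(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-cell mean over iterations (NaN-aware): the mean simulated gradient."""
    stacked = pd.concat(tables, keys=range(len(tables)), names=["iteration"])
    return stacked.groupby(level="cell", sort=False).mean().loc[tables[0].index]


def spearman_summary(
    table: pd.DataFrame, occupied_only: bool = True
) -> tuple[pd.DataFrame, float]:
    """Pairwise Spearman correlations between metrics, and their mean |rho|.

    Correlations use pairwise-complete cells (average ranks for ties),
    need at least 3 complete cells per pair, and by default consider
    only occupied cells (richness >= 1). Returns ``(matrix, mean_abs)``
    where the mean is over defined off-diagonal entries.
    """
    df = table
    if occupied_only:
        df = df[df["richness"] >= 1]
    corr = df.corr(method="spearman", min_periods=3)
    vals = corr.to_numpy(dtype=float).copy()
    iu = np.triu_indices_from(vals, k=1)
    off = vals[iu]
    mean_abs = float(np.nanmean(np.abs(off))) if np.isfinite(off).any() else float("nan")
    return corr, mean_abs
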