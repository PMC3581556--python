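"""Spreading-dye range randomization.

The null model conserves each species' range size and cohesion but
nothing else: a seed cell is drawn uniformly from the domain, then the
range grows by repeatedly letting a uniformly chosen occupied cell send
a disperser to a uniformly chosen adjacent in-domain cell, which joins
the range if unoccupied, until the empirical size is reached. Repeating
the placement for every species yields one randomized presence matrix;
an ensemble of such matrices defines the expected diversity gradients
under random range placement.

The growth loop is compiled with numba: ensembles multiply thousands of
range placements, and the sequential disperser process is irreducibly
iterative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numba import njit

from .grid import Domain, PresenceMatrix

DISPERSER = "disperser"  # sequential occupied-cell -> neighbor steps
FRONTIER = "frontier"    # uniform over unoccupied neighbors of the range

_SEED_MOD = 2**31


class UnreachableSizeError(RuntimeError):
    """No seed component can host a range of the requested size."""


@dataclass(frozen=True)
class SpreadConfig:
    """Simulation settings for a randomization ensemble."""

    adjacency: str = "rook"
    rng_seed: int = 0
    n_iterations: int = 1000
    max_restarts: int = 100
    scheme: str = DISPERSER

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.max_restarts < 1:
            raise ValueError("max_restarts must be >= 1")
        if self.scheme not in (DISPERSER, FRONTIER):
            raise ValueError(f"unknown growth scheme: {self.scheme!r}")


@dataclass
class SimulatedEnsemble:
    """Ordered randomized presence matrices plus their substream seeds."""

    matrices: list
    iteration_seeds: list

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    def __getitem__(self, i):
        return self.matrices[i]


@njit(cache=True)
def _component_size_nb(nbr, deg, seed, n):  # pragma: no cover - exercised via kernel
    seen = np.zeros(n, np.bool_)
    stack = np.empty(n, np.int64)
    seen[seed] = True
    stack[0] = seed
    top = 1
    count = 1
    while top > 0:
        top -= 1
        i = stack[top]
        for k in range(deg[i]):
            j = nbr[i, k]
            if not seen[j]:
                seen[j] = True
                count += 1
                stack[top] = j
                top += 1
    return count


@njit(cache=True)
def _spread_kernel(nbr, deg, target, n, max_restarts, seed, accept, use_accept):
    """Grow one range; returns occupied cell ids or [-1] on failure."""
    np.random.seed(seed)
    for _ in range(max_restarts):
        while True:  # uniform seed cell, thinned by the acceptance field
            s = np.random.randint(0, n)
            if not use_accept or np.random.random() < accept[s]:
                break
        occ = np.empty(target, np.int64)
        occ[0] = s
        if target == 1:
            return occ
        if _component_size_nb(nbr, deg, s, n) < target:
            continue  # fragmented domain: this seed's component is too small
        occupied = np.zeros(n, np.bool_)
        occupied[s] = True
        n_occ = 1
        # budget guards against stalls when an acceptance field leaves the
        # target practically unreachable from this seed; a stalled growth
        # is discarded and reseeded like a too-small component
        budget = 2000 * target + 100000
        attempts = 0
        while n_occ < target and attempts < budget:
            attempts += 1
            i = occ[np.random.randint(0, n_occ)]
            d = deg[i]
            if d == 0:
                continue
            j = nbr[i, np.random.randint(0, d)]
            if occupied[j]:
                continue
            if use_accept and np.random.random() >= accept[j]:
                continue
            occupied[j] = True
            occ[n_occ] = j
            n_occ += 1
        if n_occ == target:
            return occ
    return np.full(1, -1, np.int64)


def _grow_frontier(domain, target, rng, accept=None):
    """Uniform accretion over the current range's unoccupied neighbors."""
    nbr, deg = domain.neighbor_arrays()
    n = domain.n_cells
    while True:
        seed = int(rng.random() * n)
        if accept is None or rng.random() < accept[seed]:
            break
    occ = [seed]
    if target == 1:
        return occ
    occupied = np.zeros(n, dtype=bool)
    occupied[seed] = True
    in_frontier = np.zeros(n, dtype=bool)
    frontier = []

    def push(cell):
        for j in nbr[cell, : deg[cell]]:
            if not occupied[j] and not in_frontier[j]:
                in_frontier[j] = True
                frontier.append(int(j))

    push(seed)
    while len(occ) < target:
        if not frontier:
            return None  # trapped: seed component exhausted
        idx = int(rng.random() * len(frontier))
        j = frontier[idx]
        if accept is not None and rng.random() >= accept[j]:
            continue
        frontier[idx] = frontier[-1]
        frontier.pop()
        in_frontier[j] = False
        occupied[j] = True
        occ.append(int(j))
        push(j)
    return occ


def spread_range(
    domain: Domain,
    target_size: int,
    rng: np.random.Generator,
    scheme: str = DISPERSER,
    max_restarts: int = 100,
    accept: np.ndarray | None = None,
) -> set:
    """Grow one cohesive random range of exactly ``target_size`` cells.

    ``accept`` optionally gives a per-cell acceptance probability applied
    to every candidate cell (seed included, by rejection), used by the
    environmentally structured alternative model; ``None`` is the pure
    null. Returns a set of cell ids, connected under the domain's
    adjacency rule.
    """
    n = domain.n_cells
    if not 1 <= target_size <= n:
        raise ValueError(f"target_size {target_size} outside [1, {n}]")
    nbr, deg = domain.neighbor_arrays()
    if scheme == FRONTIER:
        for _ in range(max_restarts):
            out = _grow_frontier(domain, target_size, rng, accept=accept)
            if out is not None:
                return set(out)
        raise UnreachableSizeError(
            f"no connected component reached size {target_size} after {max_restarts} restarts"
        )
    kernel_seed = int(rng.integers(_SEED_MOD))
    use_accept = accept is not None
    acc = np.asarray(accept, dtype=np.float64) if use_accept else np.empty(0)
    out = _spread_kernel(
        nbr, deg, int(target_size), n, int(max_restarts), kernel_seed, acc, use_accept
    )
    if out[0] < 0:
        raise UnreachableSizeError(
            f"no connected component reached size {target_size} after {max_restarts} restarts"
        )
    return set(int(c) for c in out)


def randomize_assemblage(
    domain: Domain,
    sizes: Mapping[str, int],
    rng: np.random.Generator,
    scheme: str = DISPERSER,
    max_restarts: int = 100,
    accept_by_species: Mapping[str, np.ndarray] | None = None,
) -> PresenceMatrix:
    """One independent spread per species; identities (hence all trait,
    tree and guild links) are untouched — only placement is randomized."""
    species = sorted(sizes)
    values = np.zeros((domain.n_cells, len(species)), dtype=bool)
    for j, sp in enumerate(species):
        accept = None if accept_by_species is None else accept_by_species.get(sp)
        try:
            cells = spread_range(
                domain, int(sizes[sp]), rng, scheme=scheme,
                max_restarts=max_restarts, accept=accept,
            )
        except UnreachableSizeError as exc:
            raise UnreachableSizeError(f"species {sp!r}: {exc}") from exc
        values[list(cells), j] = True
    return PresenceMatrix(values, domain, species)


def iteration_rng(rng_seed: int, iteration: int) -> np.random.Generator:
    """Independent, reproducible substream for one ensemble iteration."""
    return np.random.default_rng(np.random.SeedSequence([int(rng_seed), int(iteration)]))


def run_ensemble(
    domain: Domain,
    sizes: Mapping[str, int],
    config: SpreadConfig,
) -> SimulatedEnsemble:
    """``n_iterations`` independent randomized matrices.

    Iteration ``i`` uses an RNG substream derived from ``(rng_seed, i)``,
    so ensembles are bit-reproducible and individual iterations can be
    regenerated in isolation.
    """
    matrices = []
    seeds = []
    for i in range(config.n_iterations):
        rng = iteration_rng(config.rng_seed, i)
        try:
            pm = randomize_assemblage(
                domain, sizes, rng, scheme=config.scheme, max_restarts=config.max_restarts
            )
        except UnreachableSizeError as exc:
            raise UnreachableSizeError(f"iteration {i}: {exc}") from exc
        matrices.append(pm)
        seeds.append((config.rng_seed, i))
    return SimulatedEnsemble(matrices, seeds)
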