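"""Gridded domains, species ranges and presence matrices.

The bounded domain is the arena inside which the null model randomizes
range placement. Cells live on an ``n_rows x n_cols`` lattice (``row``
indexes the latitudinal axis, ``col`` the longitudinal one) but the cell
set need not be rectangular: coastline-like masks are allowed. Every
other structure in the package — ranges, presence matrices, per-cell
metric tables — is indexed by the domain's cell ids, which are assigned
in row-major order over the mask cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

ROOK = "rook"
QUEEN = "queen"

_ROOK_STEPS = ((-1, 0), (1, 0), (0, -1), (0, 1))
_QUEEN_STEPS = _ROOK_STEPS + ((-1, -1), (-1, 1), (1, -1), (1, 1))


class DomainMismatchError(ValueError):
    """A range references a cell outside the domain."""


@dataclass(frozen=True)
class GridCell:
    """A single grid cell: unique ``id`` plus lattice coordinates."""

    id: int
    row: int
    col: int


class Domain:
    """A set of grid cells with a neighborhood structure.

    Parameters
    ----------
    cells:
        Iterable of ``(row, col)`` pairs. Ids are assigned in row-major
        order of the sorted unique pairs.
    n_rows, n_cols:
        Lattice extent; inferred from the cells when omitted.
    adjacency:
        ``"rook"`` (4-neighbor, default) or ``"queen"`` (8-neighbor).
    """

    def __init__(
        self,
        cells: Iterable[tuple[int, int]],
        n_rows: int | None = None,
        n_cols: int | None = None,
        adjacency: str = ROOK,
    ):
        pairs = sorted(set((int(r), int(c)) for r, c in cells))
        if not pairs:
            raise ValueError("domain must contain at least one cell")
        if adjacency not in (ROOK, QUEEN):
            raise ValueError(f"unknown adjacency rule: {adjacency!r}")
        self.rows = np.array([p[0] for p in pairs], dtype=np.int64)
        self.cols = np.array([p[1] for p in pairs], dtype=np.int64)
        if self.rows.min() < 0 or self.cols.min() < 0:
            raise ValueError("cell coordinates must be nonnegative")
        self.n_rows = int(n_rows) if n_rows is not None else int(self.rows.max()) + 1
        self.n_cols = int(n_cols) if n_cols is not None else int(self.cols.max()) + 1
        if self.rows.max() >= self.n_rows or self.cols.max() >= self.n_cols:
            raise ValueError("cells fall outside the declared lattice extent")
        self.adjacency = adjacency
        self._id_of = {p: i for i, p in enumerate(pairs)}
        self._neighbors_cache: tuple[np.ndarray, np.ndarray] | None = None

    # -- basic protocol ------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.rows)

    def __len__(self) -> int:
        return self.n_cells

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in self._id_of

    def cell_id(self, row: int, col: int) -> int:
        return self._id_of[(int(row), int(col))]

    def cell(self, cell_id: int) -> GridCell:
        return GridCell(int(cell_id), int(self.rows[cell_id]), int(self.cols[cell_id]))

    def cell_labels(self) -> list[str]:
        """Stable export labels ``r{row}c{col}`` in id order."""
        return [f"r{r}c{c}" for r, c in zip(self.rows, self.cols)]

    # -- adjacency -----------------------------------------------------
    def neighbor_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded neighbor table ``(nbr, deg)``.

        ``nbr`` has shape ``(n_cells, max_degree)`` with in-domain
        neighbor ids left-justified and ``-1`` padding; ``deg[i]`` is the
        number of valid entries in row ``i``.
        """
        if self._neighbors_cache is None:
            steps = _ROOK_STEPS if self.adjacency == ROOK else _QUEEN_STEPS
            max_deg = len(steps)
            nbr = np.full((self.n_cells, max_deg), -1, dtype=np.int64)
            deg = np.zeros(self.n_cells, dtype=np.int64)
            for i in range(self.n_cells):
                r, c = int(self.rows[i]), int(self.cols[i])
                k = 0
                for dr, dc in steps:
                    j = self._id_of.get((r + dr, c + dc))
                    if j is not None:
                        nbr[i, k] = j
                        k += 1
                deg[i] = k
            self._neighbors_cache = (nbr, deg)
        return self._neighbors_cache

    def is_connected(self, cell_ids: Sequence[int] | None = None) -> bool:
        """Flood-fill connectivity check of a cell subset (default: whole domain)."""
        ids = np.arange(self.n_cells) if cell_ids is None else np.asarray(sorted(cell_ids))
        if len(ids) == 0:
            return True
        member = np.zeros(self.n_cells, dtype=bool)
        member[ids] = True
        nbr, deg = self.neighbor_arrays()
        seen = np.zeros(self.n_cells, dtype=bool)
        stack = [int(ids[0])]
        seen[ids[0]] = True
        count = 1
        while stack:
            i = stack.pop()
            for j in nbr[i, : deg[i]]:
                if member[j] and not seen[j]:
                    seen[j] = True
                    count += 1
                    stack.append(int(j))
        return count == len(ids)

    def subset(self, cell_ids: Sequence[int]) -> "Domain":
        """New Domain restricted to ``cell_ids`` (ids are re-assigned)."""
        pairs = [(int(self.rows[i]), int(self.cols[i])) for i in cell_ids]
        return Domain(pairs, self.n_rows, self.n_cols, self.adjacency)


@dataclass
class RangeSet:
    """Mapping species id -> set of occupied domain cell ids."""

    ranges: Dict[str, frozenset]

    def __post_init__(self):
        clean = {}
        for sp, cells in self.ranges.items():
            cells = frozenset(int(c) for c in cells)
            if not cells:
                raise ValueError(f"species {sp!r} has an empty range")
            clean[str(sp)] = cells
        self.ranges = clean

    @property
    def species(self) -> list[str]:
        return sorted(self.ranges)

    def sizes(self) -> Dict[str, int]:
        return {sp: len(cells) for sp, cells in self.ranges.items()}

    def __len__(self) -> int:
        return len(self.ranges)


class PresenceMatrix:
    """Boolean cells x species incidence matrix tied to a Domain."""

    def __init__(self, values: np.ndarray, domain: Domain, species: Sequence[str]):
        values = np.asarray(values, dtype=bool)
        if values.shape != (domain.n_cells, len(species)):
            raise ValueError(
                f"presence matrix shape {values.shape} does not match "
                f"({domain.n_cells} cells, {len(species)} species)"
            )
        self.values = values
        self.domain = domain
        self.species = list(species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def richness(self) -> np.ndarray:
        """Per-cell species count (row sums)."""
        return self.values.sum(axis=1).astype(np.int64)

    def range_sizes(self) -> np.ndarray:
        """Per-species occupied-cell count (column sums)."""
        return self.values.sum(axis=0).astype(np.int64)

    def occupied_cells(self) -> np.ndarray:
        """Ids of cells holding at least one species, in id (row-major) order."""
        return np.flatnonzero(self.values.any(axis=1)) if self.n_species else np.array([], dtype=np.int64)

    def species_at(self, cell_id: int) -> list[str]:
        return [self.species[j] for j in np.flatnonzero(self.values[cell_id])]

    def to_rangeset(self) -> RangeSet:
        return RangeSet(
            {sp: frozenset(np.flatnonzero(self.values[:, j]).tolist()) for j, sp in enumerate(self.species)}
        )

    def to_frame(self) -> pd.DataFrame:
        """0/1 DataFrame indexed by cell label, one column per species."""
        return pd.DataFrame(
            self.values.astype(np.int8),
            index=pd.Index(self.domain.cell_labels(), name="cell"),
            columns=self.species,
        )


def build_presence_matrix(ranges: RangeSet, domain: Domain) -> PresenceMatrix:
    """Incidence matrix with entry (c, s) true iff cell c is in species s's range."""
    species = ranges.species
    values = np.zeros((domain.n_cells, len(species)), dtype=bool)
    for j, sp in enumerate(species):
        cells = np.fromiter(ranges.ranges[sp], dtype=np.int64)
        if len(cells) and (cells.min() < 0 or cells.max() >= domain.n_cells):
            bad = [int(c) for c in cells if c < 0 or c >= domain.n_cells]
            raise DomainMismatchError(
                f"species {sp!r} occupies cells outside the domain: {sorted(bad)[:5]}"
            )
        values[cells, j] = True
    return PresenceMatrix(values, domain, species)


def richness(pm: PresenceMatrix) -> np.ndarray:
    return pm.richness()


def occupied_cells(pm: PresenceMatrix) -> np.ndarray:
    return pm.occupied_cells()


def domain_from_ranges(ranges: RangeSet, mask: Domain, rule: str = "latitudinal-band") -> Domain:
    """Sub-domain of ``mask`` bounded by the species' occupied rows.

    ``latitudinal-band`` (default): all mask cells whose row lies within
    the min/max row occupied by any species. ``footprint``: exactly the
    union of occupied cells.
    """
    if not ranges.ranges:
        raise ValueError("cannot derive a domain from an empty RangeSet")
    occ = sorted(set().union(*ranges.ranges.values()))
    occ = np.asarray(occ, dtype=np.int64)
    if occ.max() >= mask.n_cells:
        raise DomainMismatchError("ranges reference cells outside the mask")
    if rule == "footprint":
        return mask.subset(occ)
    if rule != "latitudinal-band":
        raise ValueError(f"unknown domain rule: {rule!r}")
    lo, hi = mask.rows[occ].min(), mask.rows[occ].max()
    keep = np.flatnonzero((mask.rows >= lo) & (mask.rows <= hi))
    return mask.subset(keep)


def remap_rangeset(ranges: RangeSet, src: Domain, dst: Domain) -> RangeSet:
    """Translate range cell ids between domains via (row, col) coordinates.

    Needed after :func:`domain_from_ranges`, which re-assigns ids on the
    restricted cell set. Raises if a range cell is absent from ``dst``.
    """
    out = {}
    for sp, cells in ranges.ranges.items():
        mapped = set()
        for c in cells:
            pair = (int(src.rows[c]), int(src.cols[c]))
            if pair not in dst:
                raise DomainMismatchError(
                    f"species {sp!r} occupies cell {pair} outside the target domain"
                )
            mapped.add(dst.cell_id(*pair))
        out[sp] = frozenset(mapped)
    return RangeSet(out)
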