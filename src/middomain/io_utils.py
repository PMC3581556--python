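"""Readers and writers for the package's plain-text interchange formats.

All tabular data are CSV (pandas), trees are Newick (dendropy), reports
are JSON. Domains may be given either as a 0/1 grid (one line per row)
or long-format ``row,col`` pairs; ranges are long-format
``species_id,row,col``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .functional import GuildTable
from .grid import Domain, PresenceMatrix, RangeSet
from .phenetic import TraitMatrix
from .phylo import Phylogeny

FLOAT_FMT = "%.10g"


# -- domain ----------------------------------------------------------------

def read_domain(path, adjacency: str = "rook") -> Domain:
    """Domain from CSV: a 0/1 grid, or long format with a header row,col."""
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if first.replace(" ", "").lower().startswith("row,col"):
        df = pd.read_csv(path)
        return Domain(list(zip(df["row"], df["col"])), adjacency=adjacency)
    grid = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    cells = [(r, c) for r in range(grid.shape[0]) for c in range(grid.shape[1]) if grid[r, c]]
    return Domain(cells, grid.shape[0], grid.shape[1], adjacency)


def write_domain(domain: Domain, path) -> None:
    """Write the 0/1 grid representation."""
    grid = np.zeros((domain.n_rows, domain.n_cols), dtype=int)
    grid[domain.rows, domain.cols] = 1
    np.savetxt(path, grid, fmt="%d", delimiter=",")


# -- ranges ----------------------------------------------------------------

def read_ranges(path, domain: Domain) -> RangeSet:
    """Long-format CSV species_id,row,col -> RangeSet of domain cell ids."""
    df = pd.read_csv(path, dtype={"species_id": str})
    out: dict = {}
    for sp, grp in df.groupby("species_id", sort=True):
        cells = set()
        for r, c in zip(grp["row"], grp["col"]):
            if (int(r), int(c)) not in domain:
                raise ValueError(f"species {sp!r}: cell ({r},{c}) outside the domain")
            cells.add(domain.cell_id(int(r), int(c)))
        out[sp] = frozenset(cells)
    return RangeSet(out)


def write_ranges(ranges: RangeSet, domain: Domain, path) -> None:
    rows = []
    for sp in ranges.species:
        for cid in sorted(ranges.ranges[sp]):
            rows.append((sp, int(domain.rows[cid]), int(domain.cols[cid])))
    pd.DataFrame(rows, columns=["species_id", "row", "col"]).to_csv(path, index=False)


def write_presence(pm: PresenceMatrix, path) -> None:
    pm.to_frame().to_csv(path)


# -- species attribute tables ---------------------------------------------

def read_guilds(path, vocabulary=None) -> GuildTable:
    df = pd.read_csv(path, dtype=str)
    assignments = dict(zip(df["species_id"], df["guild"]))
    if vocabulary is None:
        vocabulary = tuple(sorted(set(assignments.values())))
    return GuildTable(assignments, vocabulary)


def write_guilds(guilds: GuildTable, path) -> None:
    pd.DataFrame(
        [(sp, guilds.assignments[sp]) for sp in guilds.species],
        columns=["species_id", "guild"],
    ).to_csv(path, index=False)


def read_traits(path, log_transform: bool = False) -> TraitMatrix:
    df = pd.read_csv(path, index_col="species_id")
    if log_transform:
        df = np.log(df)
    return TraitMatrix(df)


def write_traits(traits: TraitMatrix, path) -> None:
    traits.frame.to_csv(path, float_format=FLOAT_FMT)


def read_tree(path) -> Phylogeny:
    return Phylogeny.from_file(path)


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(
        tree.tree.as_string(schema="newick", suppress_rooting=True)
    )


# -- metric tables and reports ---------------------------------------------

def write_metric_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, float_format=FLOAT_FMT)


def read_metric_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def cross_validate_species(
    ranges: RangeSet, tree: Phylogeny, guilds: GuildTable, traits: TraitMatrix
) -> dict:
    """Report species-id set mismatches across the four inputs."""
    sets = {
        "ranges": set(ranges.species),
        "tree": set(tree.tips),
        "guilds": set(guilds.species),
        "traits": set(traits.species),
    }
    common = set.intersection(*sets.values())
    report = {"n_common": len(common), "mismatches": {}}
    for name, s in sets.items():
        extra, missing = sorted(s - common), sorted(common - s)
        if extra:
            report["mismatches"][name] = {"only_here": extra}
    report["consistent"] = all(s == sets["ranges"] for s in sets.values())
    return report
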