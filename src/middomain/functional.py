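"""Functional (trophic-guild) diversity of cell assemblages.

Species carry a single diet guild from a fixed vocabulary (six guilds in
the motivating bat system: aerial insectivores, frugivores, gleaning
animalivores, nectarivores, piscivores, sanguinivores). Per-cell
functional structure is summarized by the guild count vector, from which
three indices follow: guild richness, Shannon diversity of guild
proportions, and Camargo evenness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np

DEFAULT_GUILDS = (
    "aerial_insectivore",
    "frugivore",
    "gleaning_animalivore",
    "nectarivore",
    "piscivore",
    "sanguinivore",
)


class UnknownSpeciesError(KeyError):
    pass


@dataclass
class GuildTable:
    """species id -> guild label, with a declared guild vocabulary."""

    assignments: Dict[str, str]
    vocabulary: Sequence[str] = DEFAULT_GUILDS

    def __post_init__(self):
        self.vocabulary = tuple(self.vocabulary)
        vocab = set(self.vocabulary)
        for sp, g in self.assignments.items():
            if g not in vocab:
                raise ValueError(f"species {sp!r} has guild {g!r} outside the vocabulary")
        self._guild_pos = {g: i for i, g in enumerate(self.vocabulary)}

    @property
    def species(self) -> list:
        return sorted(self.assignments)

    def indicator(self, species_order: Sequence[str]) -> np.ndarray:
        """(n_species, n_guilds) one-hot matrix in the given species order."""
        M = np.zeros((len(species_order), len(self.vocabulary)), dtype=np.int64)
        for i, sp in enumerate(species_order):
            if sp not in self.assignments:
                raise UnknownSpeciesError(f"species {sp!r} missing from the guild table")
            M[i, self._guild_pos[self.assignments[sp]]] = 1
        return M


def guild_counts(taxa: Iterable[str], guilds: GuildTable) -> np.ndarray:
    """Species count per guild over the full vocabulary; sums to |taxa|."""
    counts = np.zeros(len(guilds.vocabulary), dtype=np.int64)
    for sp in taxa:
        if sp not in guilds.assignments:
            raise UnknownSpeciesError(f"species {sp!r} missing from the guild table")
        counts[guilds._guild_pos[guilds.assignments[sp]]] += 1
    return counts


def functional_richness(counts: np.ndarray) -> int:
    """Number of guilds represented by at least one species."""
    return int(np.count_nonzero(np.asarray(counts)))


def shannon_fd(counts: np.ndarray) -> float:
    """Shannon index H = -sum p_g ln p_g over guilds present (natural log)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return math.nan
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def camargo_evenness(counts: np.ndarray, all_guilds: bool = False) -> float:
    """Camargo evenness E = 1 - sum_{g<h} |p_g - p_h| / G.

    G counts guilds present in the assemblage by default, making the
    index independent of guild richness; ``all_guilds=True`` normalizes
    by the full vocabulary instead (sensitivity variant). Equals 1 iff
    all present-guild counts are equal.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return math.nan
    G = len(counts) if all_guilds else int(np.count_nonzero(counts))
    p = (counts if all_guilds else counts[counts > 0]) / total
    diff = np.abs(p[:, None] - p[None, :]).sum() / 2.0  # unordered pairs
    return float(1.0 - diff / G)
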