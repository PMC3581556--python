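import numpy as np
import pandas as pd
import pytest

from middomain.functional import GuildTable
from middomain.grid import Domain, RangeSet, build_presence_matrix
from middomain.phenetic import TraitMatrix
from middomain.phylo import Phylogeny

WORKED_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture(scope="session")
def worked_tree():
    """Three-tip tree whose PD/PSV/PSC values are known by hand."""
    return Phylogeny.from_newick(WORKED_NEWICK)


@pytest.fixture()
def line_domain():
    """1x21 linear domain used for mid-domain checks."""
    return Domain([(0, c) for c in range(21)], 1, 21)


@pytest.fixture()
def tiny_domain():
    return Domain([(r, c) for r in range(3) for c in range(3)], 3, 3)


@pytest.fixture()
def tiny_world():
    """Hand-built 4-species world on a 3x3 domain, fully cross-resolvable."""
    domain = Domain([(r, c) for r in range(3) for c in range(3)], 3, 3)
    ranges = RangeSet(
        {
            "sp1": {0, 1, 3},
            "sp2": {4, 5},
            "sp3": {0, 4, 8},
            "sp4": {6, 7, 8},
        }
    )
    tree = Phylogeny.from_newick("((sp1:1,sp2:1):1,(sp3:1.5,sp4:1.5):0.5);")
    guilds = GuildTable(
        {"sp1": "frugivore", "sp2": "frugivore", "sp3": "nectarivore", "sp4": "piscivore"}
    )
    traits = TraitMatrix(
        pd.DataFrame(
            {
                "t1": [0.0, 0.1, 0.5, 0.9],
                "t2": [1.0, 1.2, 1.1, 0.7],
            },
            index=pd.Index(["sp1", "sp2", "sp3", "sp4"], name="species_id"),
        )
    )
    pm = build_presence_matrix(ranges, domain)
    return dict(domain=domain, ranges=ranges, tree=tree, guilds=guilds, traits=traits, pm=pm)
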