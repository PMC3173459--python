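"""Shared fixtures: a small synthetic world and its NB models.

The default world (3 phyla x 2 families x 2 genera x 3 species, one strain
each, 50 kb single-contig genomes) is expensive enough to build that it is
shared session-wide; tests must not mutate it.
"""

from __future__ import annotations

import pytest

from fragtax import build_nb_model
from fragtax.simdata import build_world
from fragtax.taxonomy import Lineage, TaxonomyTree, load_taxonomy


@pytest.fixture(scope="session")
def world():
    return build_world(seed=1)


@pytest.fixture(scope="session")
def models(world):
    """NB models (n=10) of every genome in the default world, by genome id."""
    return {
        gid: build_nb_model(gid, contigs, 10)
        for gid, contigs in sorted(world.genomes.items())
    }


@pytest.fixture(scope="session")
def model_list(models):
    return [models[g] for g in sorted(models)]


def make_tree(rows) -> TaxonomyTree:
    """Taxonomy from abbreviated rows: (genome_id, *labels) padded by repetition
    of the genome id at missing deep ranks is NOT done — callers give 8 labels."""
    return load_taxonomy(rows)


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    """Six genomes: two genera in one family, a second family, a second phylum."""
    rows = [
        ["g1", "d1", "p1", "c1", "o1", "f1", "gen1", "sp1", "g1"],
        ["g2", "d1", "p1", "c1", "o1", "f1", "gen1", "sp2", "g2"],
        ["g3", "d1", "p1", "c1", "o1", "f1", "gen2", "sp3", "g3"],
        ["g4", "d1", "p1", "c1", "o1", "f2", "gen3", "sp4", "g4"],
        ["g5", "d1", "p2", "c2", "o2", "f3", "gen4", "sp5", "g5"],
        ["g6", "d1", "p1", "c1", "o1", "f1", "gen1", "sp2", "g6"],
    ]
    return load_taxonomy(rows)


@pytest.fixture
def lineage_of(toy_tree):
    def get(gid: str) -> Lineage:
        return toy_tree.lineage(gid)

    return get
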