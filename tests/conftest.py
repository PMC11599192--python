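import pytest

from cd28fam.catalog import load_catalog
from cd28fam.simulate import (
    SimProteinConfig,
    marker_context_table,
    simulate_family_protein,
)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def exemplar(catalog):
    """Factory: zero-divergence (by default) synthetic receptor for a family."""

    def make(family, seed=0, divergence=0.0, protect_motifs=True, **kwargs):
        config = SimProteinConfig(
            family=family,
            divergence=divergence,
            protect_motifs=protect_motifs,
            seed=seed,
            **kwargs,
        )
        return simulate_family_protein(config, profiles=catalog)

    return make


@pytest.fixture(scope="session")
def context_for(catalog):
    """Factory: genomic context (gene table, gene name) in a family's marker
    neighborhood."""

    def make(family, gene_name="cand"):
        return marker_context_table(family, gene_name, profiles=catalog), gene_name

    return make
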