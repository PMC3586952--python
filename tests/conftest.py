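import numpy as np
import pytest

from phyloscan.geneorder import Gene, GeneOrderGenome
from phyloscan.simgen import fungal_species_tree


@pytest.fixture(scope="session")
def fungal():
    """Default 22-species deep-fungal tree and its group map."""
    return fungal_species_tree()


@pytest.fixture
def colinear_genome():
    """Factory for same-strand colinear genomes with 1:1 families/tokens."""

    def make(name: str, n: int, strand: str = "+") -> GeneOrderGenome:
        genes = [Gene(f"{name}_g{i}", i, strand, f"F{i}", f"L{i}")
                 for i in range(n)]
        return GeneOrderGenome(name, {"c1": genes})

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
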