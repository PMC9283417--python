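import numpy as np
import pytest

from hexkit.core import HAPLOTYPES, SUBGENOMES, ChromosomeID, GenomeStructure
from hexkit.te_bias import TETable


def make_structure(n_groups: int, length: int = 50_000_000) -> GenomeStructure:
    entries = [
        (ChromosomeID(g, s, h), length)
        for g in range(1, n_groups + 1)
        for s in SUBGENOMES
        for h in HAPLOTYPES
    ]
    return GenomeStructure(entries, n_groups=n_groups)


@pytest.fixture
def toy_structure() -> GenomeStructure:
    """One homeologous group: 6 chromosomes, 50 Mbp each."""
    return make_structure(1)


@pytest.fixture
def full_structure() -> GenomeStructure:
    """The complete 25-group, 150-chromosome karyotype."""
    return make_structure(25)


def table_from_triplets(structure, family, triplet_values):
    """Build a TETable assigning (f_a, f_b, f_c) per (group, subgenome)."""
    counts = {}
    for (g, s), (fa, fb, fc) in triplet_values.items():
        for h, v in zip("abc", (fa, fb, fc)):
            counts[(family, ChromosomeID(g, s, h))] = v
    return TETable(counts, structure)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
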