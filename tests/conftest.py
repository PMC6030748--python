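import numpy as np
import pytest

from hydropop.io import GenotypeTable, Locus


def table_from_genotypes(genos_per_pop, motif=2, locus_names=None):
    """Build a GenotypeTable from {pop: [[(a1, a2), ...] per locus-major row]}.

    ``genos_per_pop`` maps population -> list of individuals, each a list of
    (a1, a2) tuples (one per locus).
    """
    inds, pops, rows = [], [], []
    n_loci = None
    k = 0
    for pop, individuals in genos_per_pop.items():
        for geno in individuals:
            k += 1
            inds.append(f"{pop}_{k}")
            pops.append(pop)
            rows.append(list(geno))
            n_loci = len(geno)
    names = locus_names or [f"L{j + 1}" for j in range(n_loci)]
    loci = [Locus(nm, motif_length=motif) for nm in names]
    return GenotypeTable(inds, loci, np.array(rows, dtype=np.int32), pops)


@pytest.fixture(scope="session")
def study_fixture():
    from hydropop.fixture import make_study_fixture

    return make_study_fixture(20260915)


@pytest.fixture
def two_pop_table():
    rng = np.random.default_rng(7)
    genos = {}
    for pop, base in (("A", 100), ("B", 104)):
        members = []
        for _ in range(15):
            members.append(
                [tuple(sorted(base + 2 * rng.integers(0, 4, size=2))) for _ in range(5)]
            )
        genos[pop] = members
    return table_from_genotypes(genos)
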