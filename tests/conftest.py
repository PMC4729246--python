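import numpy as np
import pytest

from clonescape.distances import DistanceMatrix
from clonescape.genotypes import GenotypeTable


def random_distance_matrix(n, rng, kind="generic", dim=3):
    """Distance matrix of random points — a generic exchangeable input."""
    pts = rng.standard_normal((n, dim))
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix([f"P{i}" for i in range(n)], squareform(pdist(pts)), kind)


def table_from_sets(calls, populations=None, ploidy=6, loci=None):
    """Build a GenotypeTable from a list of per-individual lists of allele sets."""
    n = len(calls)
    n_loci = len(calls[0])
    return GenotypeTable(
        individuals=[f"i{k + 1}" for k in range(n)],
        populations=populations or ["pop1"] * n,
        loci=loci or [f"L{j + 1}" for j in range(n_loci)],
        calls=[tuple(frozenset(s) for s in row) for row in calls],
        ploidy=ploidy,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160108)
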