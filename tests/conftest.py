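import numpy as np
import pytest

from chickadmix.genotype_io import GenotypeMatrix
from chickadmix.synthetic_data import (
    SimulationDesign,
    simulate_individuals,
    simulate_parental_frequencies,
)


def make_matrix(calls, qual=None, depth=None, chrom="1"):
    """GenotypeMatrix from a nested list (individuals x loci)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loci = calls.shape
    return GenotypeMatrix(
        individuals=[f"ind{i}" for i in range(n_ind)],
        loci=[(chrom, j + 1) for j in range(n_loci)],
        calls=calls,
        site_qual=np.full(n_loci, 60.0) if qual is None else np.asarray(qual, float),
        site_depth=None if depth is None else np.asarray(depth, float),
    )


@pytest.fixture(scope="session")
def diagnostic_cohort():
    """Five ancestry classes at 500 fully diagnostic loci, plus truth freqs.

    Shared across hybrid-index tests; treat as read-only.
    """
    freqs = simulate_parental_frequencies(500, 0.15, 1.0, seed=11)
    design = SimulationDesign(
        n_loci=500,
        diagnostic_fraction=1.0,
        class_counts={"pureA": 10, "pureB": 10, "F1": 10, "BC1A": 10, "BC1B": 10},
        seed=11,
    )
    matrix, metadata = simulate_individuals(design, freqs)
    return freqs, matrix, metadata
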