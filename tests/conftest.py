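import numpy as np
import pytest

from hybridpanel.genotype_core.model import GenotypeMatrix, Individual, Locus
from hybridpanel.synthetic_data import AlleleFrequencyModel


def make_loci(n, prefix="L", chrom="1"):
    return [
        Locus(id=f"{prefix}{j + 1:03d}", chromosome=chrom, position=1000 * (j + 1),
              allele1="A", allele2="G")
        for j in range(n)
    ]


def make_matrix(calls, groups=None, loci=None, sample_types=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    groups = groups or ["g"] * n
    sample_types = sample_types or ["tissue"] * n
    return GenotypeMatrix(
        loci=loci or make_loci(L),
        individuals=[Individual(id=f"ind{i + 1}", group=groups[i],
                                sample_type=sample_types[i]) for i in range(n)],
        calls=calls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model():
    """Hand-built 6-locus frequency model with the opposite-major property."""
    loci = make_loci(6)
    p_wolf = np.array([1.0, 1.0, 0.98, 0.95, 0.85, 0.75])
    p_dog = np.array([0.25, 0.2, 0.15, 0.2, 0.12, 0.11])
    return AlleleFrequencyModel(loci=loci, p_wolf=p_wolf, p_dog=p_dog)
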