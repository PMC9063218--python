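import numpy as np
import pytest

from epinet.gwas_io import GenotypeData, SnpMeta
from epinet.synthetic import make_fixture, preset


@pytest.fixture
def tiny_gd() -> GenotypeData:
    """Six samples, four SNPs on two chromosomes, balanced phenotype."""
    snps = [
        SnpMeta("rsA", "1", 100, ("A", "G")),
        SnpMeta("rsB", "1", 200, ("C", "T")),
        SnpMeta("rsC", "2", 150, ("A", "C")),
        SnpMeta("rsD", "2", 400, ("G", "T")),
    ]
    matrix = np.array(
        [
            [0, 1, 2, 0],
            [1, 0, 1, 1],
            [2, 1, 0, 0],
            [0, 2, 1, 2],
            [1, 1, 0, 1],
            [0, 0, 2, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeData(
        samples=[f"s{i}" for i in range(6)],
        snps=snps,
        matrix=matrix,
        phenotype=np.array([1, 1, 1, 0, 0, 0]),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic input bundle shared across pipeline-level tests."""
    return make_fixture(preset("small", seed=11))
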