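import numpy as np
import pytest

from crisprwgs import ReferenceGenome, simulate_reference


@pytest.fixture(scope="session")
def small_genome() -> ReferenceGenome:
    """50-kb single-contig random genome shared across tests."""
    return simulate_reference(1, 50_000, 0.43, seed=11)


@pytest.fixture()
def toy_genome() -> ReferenceGenome:
    """Tiny hand-written genome with a homopolymer run for left-alignment tests."""
    #                 1         2         3
    #        123456789012345678901234567890123456
    seq = "ACGTACGGAAAAATCGATCGTACGCGTATATGCCGT"
    return ReferenceGenome({"chr1": seq})
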