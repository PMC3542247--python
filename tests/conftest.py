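from random import Random

import pytest

from polymeiosis import ChiasmaProcessConfig, ChromosomeSpec


@pytest.fixture
def rng():
    return Random(42)


@pytest.fixture
def cfg():
    """Chiasma process without interference (Haldane regime)."""
    return ChiasmaProcessConfig()


@pytest.fixture
def cfg_interference():
    """Gamma renewal process with interference (Kosambi regime)."""
    return ChiasmaProcessConfig(interference=True)


@pytest.fixture
def chrom100():
    """100 cM chromosome, centromere at 20% of the length, natural pairing."""
    return ChromosomeSpec("1", 100.0, 20.0)


@pytest.fixture
def chrom100_bivalent():
    return ChromosomeSpec("1", 100.0, 20.0, quadrivalent_fraction=0.0)


@pytest.fixture
def chrom100_parallel():
    return ChromosomeSpec("1", 100.0, 20.0, quadrivalent_fraction=1.0, parallel_fraction=1.0)


@pytest.fixture
def chrom100_cross():
    return ChromosomeSpec("1", 100.0, 20.0, quadrivalent_fraction=1.0, parallel_fraction=0.0)
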