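import numpy as np
import pytest

from polkin import (GeneArchitecture, GeneClass, RateSet,
                    SimulationProtocol)


@pytest.fixture(scope="session")
def stm_arch():
    return GeneArchitecture(gene_class=GeneClass.STM)


@pytest.fixture(scope="session")
def tfo_arch():
    return GeneArchitecture(gene_class=GeneClass.TFO)


@pytest.fixture(scope="session")
def small_tfo_arch():
    """Reduced transcript (4 bins) so exact CTMC solves stay fast."""
    return GeneArchitecture(gene_class=GeneClass.TFO, n_transcript_bins=4)


@pytest.fixture(scope="session")
def small_stm_arch():
    return GeneArchitecture(gene_class=GeneClass.STM, n_transcript_bins=4)


@pytest.fixture(scope="session")
def stm_rates():
    return RateSet.stm()


@pytest.fixture(scope="session")
def tfo_rates():
    return RateSet.tfo()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_protocol():
    return SimulationProtocol(n_genes=500, master_seed=42)
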