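import numpy as np
import pytest

from promdir.synthetic import SimulationConfig, generate


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (400 genes, 10 Mb), fixed seed."""
    return generate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced landscape for cheaper structural checks."""
    return generate(SimulationConfig(seed=7, n_genes=80, chrom_length=2_000_000))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
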