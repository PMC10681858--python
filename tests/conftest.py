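import numpy as np
import pytest
from hypothesis import settings

import stocirc as sc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constitutive():
    return sc.load_fixture("constitutive_1gene")


@pytest.fixture(scope="session")
def toggle():
    return sc.load_fixture("toggle_switch")


@pytest.fixture(scope="session")
def repressilator():
    return sc.load_fixture("repressilator")


@pytest.fixture(scope="session")
def two_independent_genes():
    """Two unregulated genes with different rates (disjoint subnetworks)."""
    return sc.GeneCircuit(
        sc.Topology(np.zeros((2, 2), dtype=int)),
        sc.KineticParameters(km=[10.0, 6.0], kx=[5.0, 4.0], gm=[5.0, 4.0],
                             gx=[1.0, 1.0], eps=[0.0, 0.0]),
    )
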