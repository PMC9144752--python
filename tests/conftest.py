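import numpy as np
import pytest

import rutheye as re
from rutheye.kernels import encapsulated_kernel

PLAQUES = ("CIA", "CIB", "COB", "COC")


@pytest.fixture(scope="session")
def bare_kernel():
    return re.default_kernel()


@pytest.fixture(scope="session")
def enc_kernel():
    return encapsulated_kernel()


@pytest.fixture(scope="session")
def reference():
    return re.load_reference()


@pytest.fixture(scope="session")
def cia_mod():
    return re.build_plaque(re.get_params("CIA", "modified"))


@pytest.fixture(scope="session")
def cia_mod_nodes(cia_mod):
    # 0.2 mm quadrature: accurate to well below a percent for unit tests
    return re.make_nodes(cia_mod, resolution=0.2)


@pytest.fixture(scope="session")
def cia_mod_nodes_fine(cia_mod):
    # 0.1 mm quadrature: converged reference for Monte Carlo comparisons
    # (the 0.2 mm set carries ~1.7% discretization bias at the CAX 1 mm point)
    return re.make_nodes(cia_mod, resolution=0.1)


@pytest.fixture(scope="session")
def toy_kernel():
    """4-sample kernel with simple values for hand-computed oracles."""
    return re.KernelTable(radii=np.array([1.0, 2.0, 4.0, 8.0]),
                          values=np.array([8.0, 4.0, 2.0, 1.0]),
                          r_max=8.0)
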