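import warnings

import numpy as np
import pytest

import eilowrank as ei

# Cauchy-Schwarz overshoot of the first-order covariance recipe is an
# expected, documented condition in the strong negative-reciprocity regime.
warnings.filterwarnings(
    "ignore", message="covariance sigma_nm exceeds Cauchy-Schwarz bound"
)


@pytest.fixture(scope="session")
def pop_small():
    """Small E-I partition for cheap structural tests."""
    return ei.PopulationStructure(N_E=160, N_I=40)


@pytest.fixture(scope="session")
def pop_dense():
    """Reference dense-network partition (N = 1500, 80/20 split)."""
    return ei.PopulationStructure(N_E=1200, N_I=300)


@pytest.fixture(scope="session")
def pop_sparse():
    """Reference sparse-network partition (N = 1000, 80/20 split)."""
    return ei.PopulationStructure(N_E=800, N_I=200)


@pytest.fixture(scope="session")
def het_g():
    """Cell-type-dependent variance table with ratios 1.0:0.5:0.2:0.8."""
    return np.array([[0.8, 0.4], [0.16, 0.64]])


@pytest.fixture(scope="session")
def phi():
    return ei.TransferFunction(theta=1.5)
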