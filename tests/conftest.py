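import numpy as np
import pytest

from enzymix import KineticTruth, MixtureTruth, generate_kinetic_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def guaiacol_truth():
    """Control kinetics of the peroxidase/guaiacol assay."""
    return KineticTruth(km=0.06, vmax=120.5)


@pytest.fixture
def uncompetitive_truth():
    """Lipoxygenase-style uncompetitive inhibition, linoleate kinetics."""
    return KineticTruth(km=0.007, vmax=1111.0, mechanism="uncompetitive",
                        k_effector=0.009)


@pytest.fixture
def uncompetitive_series(uncompetitive_truth):
    return generate_kinetic_series(uncompetitive_truth, [0.0045, 0.009, 0.018])


@pytest.fixture
def additive_mixture_truth():
    return MixtureTruth(dm1=0.10, dm2=0.69, m1=1.0, m2=1.0, psi=1.0)
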