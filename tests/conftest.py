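import numpy as np
import pytest

import framechannel as fc
from framechannel.fixtures import dirichlet_usage


@pytest.fixture(scope="session")
def code():
    return fc.STANDARD_CODE


@pytest.fixture(scope="session")
def uniform():
    return fc.CodonUsage.uniform()


@pytest.fixture(scope="session")
def usage():
    """A realistic non-uniform codon usage (fixed seed)."""
    return dirichlet_usage(7)


@pytest.fixture(scope="session")
def Q(usage):
    """Scaled M0 generator, kappa=2, omega=0.5, on the Dirichlet usage."""
    return fc.build_rate_matrix(fc.ModelParams(kappa=2.0, omega=0.5), usage)


@pytest.fixture(scope="session")
def dicodon(Q):
    return fc.dicodon_rate_matrix(Q)


@pytest.fixture(scope="session")
def frame_models(Q):
    return fc.all_frame_models(Q)


@pytest.fixture(scope="session")
def purifying_models(usage):
    """All frame models for the purifying scenario kappa=1, omega=0.3."""
    Q = fc.build_rate_matrix(fc.ModelParams(kappa=1.0, omega=0.3), usage)
    return fc.all_frame_models(Q)


@pytest.fixture(scope="session")
def adaptive_models(usage):
    """All frame models for the adaptive scenario kappa=1, omega=3.0."""
    Q = fc.build_rate_matrix(fc.ModelParams(kappa=1.0, omega=3.0), usage)
    return fc.all_frame_models(Q)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
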