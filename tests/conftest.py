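import numpy as np
import pytest

from hipdea.analytic import run_verification
from hipdea.synthetic import synth_population

AXIS = np.array([0.0, 0.0, -1.0])


@pytest.fixture(scope="session")
def verification_1mm():
    """The ball-and-socket benchmark at 1.0 mm edge length (reference setup)."""
    return run_verification(target_edge=1.0)


@pytest.fixture(scope="session")
def verification_by_edge():
    """Benchmark reports over a refinement sequence, keyed by edge length."""
    return {edge: run_verification(target_edge=edge) for edge in (2.0, 1.5, 1.0)}


@pytest.fixture(scope="session")
def population():
    """Seeded corresponded population with a spatially varying shared field."""
    return synth_population(n=10, seed=1)
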