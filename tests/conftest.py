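import numpy as np
import pytest

from poroindent.materials import hydrogel_parameters


@pytest.fixture(scope="session")
def params():
    """Reference (identified hydrogel) parameter set."""
    return hydrogel_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230410)


@pytest.fixture(scope="session")
def terzaghi_result():
    """Shared consolidation benchmark run (drained top, impermeable base)."""
    from poroindent.benchmark import terzaghi_benchmark
    return terzaghi_benchmark(time_factors=(0.2, 0.5))


def random_deformation_gradient(rng, scale=0.3):
    """Random admissible F with det > 0 (moderate distortion)."""
    F = np.eye(3) + scale * rng.uniform(-1.0, 1.0, (3, 3))
    if np.linalg.det(F) <= 0.05:
        F = np.eye(3) + 0.1 * rng.uniform(-1.0, 1.0, (3, 3))
    return F
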