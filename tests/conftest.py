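import numpy as np
import pytest

from ordssm import GRMItem, LinearItem, MeasurementModel

A_TRI = np.array([[0.7, 0.25], [0.0, 0.7]])


@pytest.fixture(scope="session")
def a_tri():
    """The upper-triangular study dynamics at AR=.7, CR=.25."""
    return A_TRI.copy()


@pytest.fixture(scope="session")
def grm_pair_model():
    """Two J=3 graded items, one per state."""
    return MeasurementModel(
        kind="grm",
        items=(
            GRMItem("g1", 1, 1.0, np.array([-0.5, 0.5])),
            GRMItem("g2", 2, 1.0, np.array([-0.5, 0.5])),
        ),
    )


@pytest.fixture(scope="session")
def linear_six_model():
    """Six linear items, three per state."""
    items = tuple(
        LinearItem(f"m{i+1}", 1 + (i % 2), 0.8, 0.5) for i in range(6)
    )
    return MeasurementModel(kind="linear", items=items)


def random_stationary(rng, p, radius=0.95):
    """A random matrix rescaled to spectral radius <= radius."""
    M = rng.standard_normal((p, p))
    r = np.max(np.abs(np.linalg.eigvals(M)))
    return M * (radius * rng.uniform(0.1, 1.0) / r)
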