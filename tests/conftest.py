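import numpy as np
import pytest

from dbtmc.simulate import (
    CohortSpec,
    DensityClass,
    MCClusterSpec,
    generate_anatomical_background,
    generate_breast_mask,
)


@pytest.fixture(scope="session")
def fatty():
    return DensityClass.standard("fatty")


@pytest.fixture(scope="session")
def dense():
    return DensityClass.standard("dense")


@pytest.fixture(scope="session")
def fatty_mask(fatty):
    return generate_breast_mask(128, fatty, 3)


@pytest.fixture(scope="session")
def fatty_slice(fatty_mask, fatty):
    """One contaminated-background fatty slice with known true mask."""
    return generate_anatomical_background(fatty_mask, fatty, 5)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Desk-scale cohort spec shared by determinism/partition tests."""
    return CohortSpec(n_cases=20, grid_size=64, slice_factor=0.09, seed=21,
                      cluster=MCClusterSpec(spread_px=5))


def numerical_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g
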