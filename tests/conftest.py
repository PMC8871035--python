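import numpy as np
import pytest

from ierdjpc import (
    IERDParams,
    JPCDesign,
    TwoSampleParams,
    load_coating_datasets,
    simulate_jpc,
)


@pytest.fixture(scope="session")
def coating():
    """The two scaled 72-observation coating-weight samples (TCS, BCS)."""
    return load_coating_datasets(scaled=True)


@pytest.fixture(scope="session")
def table1_design():
    """k=30, n=20, m=25, scheme (5,0^28,10): a moderately censored design."""
    return JPCDesign(m=25, n=20, k=30, removals="(5,0^28,10)")


@pytest.fixture(scope="session")
def truth():
    """The study truth (theta1, theta2, lam) = (3, 2, 2)."""
    return TwoSampleParams(3.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def sim_dataset(table1_design, truth):
    """One seeded non-degenerate simulated JPC dataset under the study truth."""
    data = simulate_jpc(
        table1_design, IERDParams(truth.theta1, truth.lam), IERDParams(truth.theta2, truth.lam), 7
    )
    assert not data.is_degenerate
    return data


@pytest.fixture(scope="session")
def toy_dataset():
    """A small k=8 record where grid quadrature over the posterior is cheap."""
    design = JPCDesign(m=6, n=6, k=8, removals=(0, 1, 0, 1, 0, 0, 1, 1))
    data = simulate_jpc(design, IERDParams(3, 2), IERDParams(2, 2), 42)
    assert not data.is_degenerate
    return data


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
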