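import numpy as np
import pytest

from breedsuit import (
    MaxentConfig,
    RasterStack,
    TrueSuitability,
    generate_covariate_stack,
    generate_world,
)
from breedsuit.geodata import GridTransform


@pytest.fixture(scope="session")
def quick_cfg():
    """Fast, exactly-specified model config for small test fits."""
    return MaxentConfig(classes={"linear", "quadratic"}, tol=1e-9,
                        max_iter=1000, background_size=2000)


@pytest.fixture(scope="session")
def small_world():
    """A 40×40 synthetic study system with a concentrated two-variable truth."""
    return generate_world(n_rows=40, n_cols=40, n_vars=3, n_points=80,
                          correlation_length=3.0, cross_correlation=0.2,
                          n_regions=5, seed=7)


@pytest.fixture(scope="session")
def small_stack():
    return generate_covariate_stack(32, 32, 3, 4.0, 0.3, seed=11)


@pytest.fixture
def truth_var1():
    return TrueSuitability({"var1": 3.0})


def make_stack(values_by_name, west=0.0, north=None, cellsize=1.0,
               missing=None):
    """Hand-built aligned stack for toy layouts."""
    first = next(iter(values_by_name.values()))
    arrs = {k: np.asarray(v, dtype=float) for k, v in values_by_name.items()}
    if north is None:
        north = np.asarray(first).shape[0] * cellsize
    if missing is None:
        missing = np.zeros(np.asarray(first).shape, dtype=bool)
    return RasterStack(layers=arrs,
                       transform=GridTransform(west, north, cellsize),
                       missing=np.asarray(missing, dtype=bool))
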