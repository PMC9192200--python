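import numpy as np
import pytest

from endospec.cohort import (
    CohortConfig,
    default_groups,
    generate_cohort,
)
from endospec.grid import build_grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_grid():
    """Reduced axis covering the fingerprint region, ~1.9 cm^-1 spacing."""
    return build_grid(650.0, 1800.0, 600)


@pytest.fixture(scope="session")
def small_cohort(small_grid):
    """30-sample cohort on the reduced grid with the default band effects."""
    cfg = CohortConfig(
        groups=default_groups(sizes={"E": 12, "NE": 10, "C": 8}),
        grid=small_grid,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def three_class_labels():
    return ["E"] * 12 + ["NE"] * 10 + ["C"] * 8
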