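import numpy as np
import pandas as pd
import pytest

from ntcpkit.cohort import CohortSpec, generate_cohort
from ntcpkit.dvh import CUMULATIVE, DIFFERENTIAL, DVHCurve


@pytest.fixture
def two_bin_curve() -> DVHCurve:
    """Half the organ at 10 Gy, half at 70 Gy."""
    return DVHCurve("p1", [10.0, 70.0], [50.0, 50.0], DIFFERENTIAL)


@pytest.fixture
def uniform_curve() -> DVHCurve:
    """Whole organ uniformly at 60 Gy (cumulative step representation)."""
    return DVHCurve("u1", [0.0, 60.0, 60.000001], [100.0, 100.0, 0.0], CUMULATIVE)


@pytest.fixture
def default_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec(seed=7))


def random_differential(rng: np.random.Generator, n_bins: int | None = None) -> DVHCurve:
    """Random differential DVH with masses summing to <= 100%."""
    n = n_bins or int(rng.integers(2, 12))
    doses = np.sort(rng.uniform(0.5, 79.5, n))
    doses += np.arange(n) * 1e-6  # enforce strict increase
    weights = rng.dirichlet(np.ones(n)) * rng.uniform(50, 100)
    return DVHCurve("r", doses, weights, DIFFERENTIAL)
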