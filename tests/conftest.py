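import numpy as np
import pandas as pd
import pytest

from morphotype.config import CohortConfig

MEASURES_SMALL = {
    "cortical_thickness": 12,
    "surface_area": 12,
    "cortical_volume": 12,
    "subcortical_volume": 12,
}


@pytest.fixture
def small_config():
    """Compact cohort with strong planted structure, for fast end-to-end checks."""
    return CohortConfig(
        n_participants=120,
        regions_per_measure=dict(MEASURES_SMALL),
        n_clusters_true=2,
        mean_shift=2.0,
        edge_effect=0.25,
        n_batches=2,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def measure_table(rng):
    """Plain correlated table, 60 participants x 8 regions, no planted structure."""
    n, r = 60, 8
    base = rng.standard_normal((n, 1))
    values = 10 + 0.6 * base + 0.8 * rng.standard_normal((n, r))
    ids = [f"P{i:03d}" for i in range(n)]
    return pd.DataFrame(values, index=pd.Index(ids, name="participant_id"),
                        columns=[f"R{j}" for j in range(r)])
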