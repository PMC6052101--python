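import numpy as np
import pandas as pd
import pytest

from cpmnet.io import CohortTable, NodeAtlas
from cpmnet.synthetic import generate_cohort, generate_stack, synthetic_atlas

SEED = 1234


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def small_atlas():
    """12-node mirror-symmetric atlas, all covered."""
    return synthetic_atlas(12, seed=SEED)


@pytest.fixture
def family_cohort():
    """10-subject cohort with an MZ pair, a DZ pair, a non-twin pair, and
    four singletons (hand-built for block tests)."""
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(10)],
            "family_id": ["F1", "F1", "F2", "F2", "F3", "F3", "F4", "F5", "F6", "F7"],
            "sibling_type": ["MZ", "MZ", "DZ", "DZ", "nontwin", "nontwin"]
            + ["nontwin"] * 4,
            "sex": [0, 0, 1, 0, 1, 1, 0, 1, 0, 1],
            "gF": np.arange(10, dtype=float),
            "motion_mean_rest1": np.full(10, 0.05),
            "motion_max_rest1": np.full(10, 0.08),
        }
    )
    return CohortTable(df)


@pytest.fixture
def signal_data():
    """Cohort + one high-signal task stack (n=60, 20 nodes) with ground truth."""
    cohort, gt = generate_cohort(
        60, seed=SEED, n_nodes=20, beta=0.15, sigma=0.25, n_planted=12
    )
    stack = generate_stack(cohort, "task1", gt)
    return cohort, gt, stack
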