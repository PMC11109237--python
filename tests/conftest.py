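import numpy as np
import pandas as pd
import pytest

from cognet.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """One default-parameter cohort of 30 participants, 10 tasks."""
    return generate_cohort(CohortSpec(n_per_group=30, seed=42))


@pytest.fixture(scope="session")
def tiny_table() -> pd.DataFrame:
    """Hand-written 3-participant, 2-task score table."""
    return pd.DataFrame(
        {
            "participant_id": ["p1", "p2", "p3", "p1", "p2", "p3"],
            "group": ["A", "A", "B", "A", "A", "B"],
            "task": ["t1", "t1", "t1", "t2", "t2", "t2"],
            "accuracy_pct": [90.0, 95.0, 100.0, 80.0, 85.0, 90.0],
            "mean_rt_ms": [600.0, 500.0, 400.0, 900.0, 800.0, 700.0],
        }
    )
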