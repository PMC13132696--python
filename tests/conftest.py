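import numpy as np
import pandas as pd
import pytest

from agetraj.bioage import MARKERS, train_reference
from agetraj.synthetic import SyntheticConfig, generate_cohort_frame, generate_reference_population


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Default study conditions at a desk-test cohort size."""
    return SyntheticConfig(n_subjects=4000, seed=20260923 % (2**31))


@pytest.fixture(scope="session")
def reference_model(small_config):
    ref = generate_reference_population(small_config, 6000, seed=101)
    return train_reference(ref)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    frame, truth = generate_cohort_frame(small_config)
    return frame, truth


@pytest.fixture(scope="session")
def oracle_baseline(small_cohort):
    """Baseline rows with the true class as the assigned label (no clustering noise)."""
    frame, _ = small_cohort
    base = frame[frame["visit_index"] == 0].copy()
    base["class_label"] = base["true_class"]
    return base


def toy_reference_frame() -> pd.DataFrame:
    """Small reference table with nonzero residual scatter on every marker."""
    rng = np.random.default_rng(7)
    age = rng.uniform(30, 70, size=200)
    data = {"age": age}
    for j, name in enumerate(MARKERS):
        data[name] = 10 + j + 0.1 * (j + 1) * age + rng.normal(0, 1.0, size=200)
    return pd.DataFrame(data)
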