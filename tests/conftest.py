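import numpy as np
import pytest

from paltriad import pipeline, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One moderately sized cohort at the default study conditions."""
    return synthetic.generate_cohort(synthetic.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_metrics(default_cohort):
    metrics, daily_pal, exclusions = pipeline.metrics_from_cohort(default_cohort)
    assert not exclusions
    return metrics, daily_pal


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
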