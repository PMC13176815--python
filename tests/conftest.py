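import numpy as np
import pytest

from pacv import GeneratorConfig, TrialTable, generate_feature_table


@pytest.fixture
def tiny_table() -> TrialTable:
    """Two participants x three trials, two features, one label each."""
    return TrialTable(
        features=np.arange(12, dtype=float).reshape(6, 2),
        labels=np.array([0, 0, 0, 1, 1, 1]),
        participant_ids=np.array(["A", "A", "A", "B", "B", "B"], dtype=object),
        trial_indices=np.array([1, 2, 3, 1, 2, 3]),
        feature_names=["fx", "fy"],
    )


@pytest.fixture(scope="session")
def cohort_table() -> TrialTable:
    """Study-shaped cohort: 72 participants, 36/36 labels, 5-10 trials each."""
    return generate_feature_table(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_623() -> TrialTable:
    """Study-shaped cohort pinned to 623 total trials (301 high / 322 low)."""
    return generate_feature_table(GeneratorConfig(seed=7, trials_per_class=(301, 322)))
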