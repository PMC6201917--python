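import numpy as np
import pytest

from gazeread import (
    SyntheticCohortSpec,
    extract_features,
    simulate_cohort,
)

PINNED_SEED = 42


@pytest.fixture(scope="session")
def pinned_cohort():
    """The study-shaped reference cohort: 17 participants x 19 texts, seed 42."""
    return simulate_cohort(SyntheticCohortSpec(seed=PINNED_SEED))


@pytest.fixture(scope="session")
def pinned_profiles(pinned_cohort):
    """Participant profiles with pipeline-extracted features for the pinned cohort."""
    return extract_features(pinned_cohort.manifest, pinned_cohort.recordings)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
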