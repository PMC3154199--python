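import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import infarctnet as inf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    return inf.GridSpec(n_slices=3, shape=(24, 24))


@pytest.fixture(scope="session")
def small_model():
    # lesion shifted into the left hemisphere of the 24x24 grid
    return inf.TissueModel(
        lesion=inf.LesionSpec(center=(12.0, 6.0), radius=3.0), csf_radius=1.5
    )


@pytest.fixture(scope="session")
def small_cohort(small_grid, small_model):
    return inf.generate_cohort(4, seed=11, model=small_model, geometry=small_grid,
                               variation=None)


@pytest.fixture(scope="session")
def small_samples(small_cohort):
    sets = [inf.preprocess_study(s, roi_threshold=1.4)[3] for s in small_cohort]
    return inf.SampleSet.concatenate(sets)


@pytest.fixture(scope="session")
def default_study():
    return inf.generate_study(seed=7)
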