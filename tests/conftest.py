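import numpy as np
import pytest

from epicad import pipeline
from epicad.phantom import PhantomSpec


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: 24mm cube, 1mm voxels, default tissue statistics."""
    return PhantomSpec(shape=(24, 24, 24), seed=11)


@pytest.fixture(scope="session")
def cohort12(small_spec):
    return pipeline.generate_phantom_cohort(small_spec, 12)


@pytest.fixture(scope="session")
def cohort_features12(cohort12):
    """(templates, per-subject feature fields, per-subject feature maps)."""
    return pipeline.build_cohort_features(cohort12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
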