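import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tractrr as tr
from tractrr.synthetic import PhantomSpec, build_phantom
from tractrr.tensor import tensor_metrics

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    """Small straight-ish tract phantom used across tracker/tensor tests."""
    return PhantomSpec(grid_shape=(24, 24, 36), tract_radius_mm=3.6)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    tfield, masks = build_phantom(small_spec)
    maps = tensor_metrics(tfield)
    v1 = tfield.principal_directions()
    return dict(spec=small_spec, field=tfield, masks=masks, maps=maps, v1=v1)


@pytest.fixture(scope="session")
def default_study():
    """One full default-configuration study (18 subjects x 2 sessions).

    Session-scoped: the end-to-end run is the expensive part of the suite and
    several checks (hemisphere contrast, reliability recovery, FA-range
    ordering, table closure) all interrogate the same result.
    """
    from tractrr.pipeline import StudyConfig, run_study

    return run_study(StudyConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
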