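import numpy as np
import pytest

from surfdetect.cohort import CohortConfig, generate_cohort
from surfdetect.mesh import build_symmetric_template


@pytest.fixture(scope="session")
def mesh_l2():
    """Coarse template: 162 vertices per hemisphere."""
    return build_symmetric_template(2, 100.0)


@pytest.fixture(scope="session")
def mesh_l3():
    """Mid-resolution template: 642 vertices per hemisphere."""
    return build_symmetric_template(3, 100.0)


@pytest.fixture(scope="session")
def mesh_l4():
    """Template at working resolution: 2562 vertices per hemisphere."""
    return build_symmetric_template(4, 100.0)


@pytest.fixture(scope="session")
def small_cohort(mesh_l2):
    """A tiny full-measure cohort for feature/classifier plumbing tests."""
    cfg = CohortConfig(
        n_controls=8, n_positive=2, n_negative=2, n_lesions=3,
        lesion_radius_mm=(20.0, 30.0), seed=42,
    )
    return generate_cohort(cfg, mesh_l2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
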