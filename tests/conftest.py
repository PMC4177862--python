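import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ccmorph.io import MidsagittalMask
from ccmorph.synthetic import CCShapeParams, CohortSpec, GroupSpec, make_cc_shape

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def filled_rect_mask() -> MidsagittalMask:
    """A filled 100 x 35 pixel block at 1 mm spacing."""
    return MidsagittalMask(np.ones((35, 100), dtype=bool), (1.0, 1.0), "rect")


@pytest.fixture
def arch_params() -> CCShapeParams:
    return CCShapeParams(
        base_mm=100.0,
        height_mm=35.27,
        region_areas_mm2=(330.0, 95.0, 100.0, 70.0, 240.0),
    )


@pytest.fixture
def arch_mask(arch_params) -> MidsagittalMask:
    return make_cc_shape(arch_params, subject_id="arch")


def small_cohort_spec(n: int = 3, seed: int = 7) -> CohortSpec:
    """Compact CB/NC cohort used by template and pipeline tests."""
    groups = {
        "CB": GroupSpec(
            n, max(n // 2, 1),
            (330.0, 95.0, 107.26, 79.4, 225.64),
            (45.0, 15.0, 21.67, 16.66, 31.7),
            109.6, 4.9,
        ),
        "NC": GroupSpec(
            n, max(n // 2, 1),
            (330.0, 95.0, 89.64, 64.16, 260.84),
            (45.0, 15.0, 16.51, 10.31, 41.7),
            113.4, 5.7,
        ),
    }
    return CohortSpec(groups=groups, seed=seed)


@pytest.fixture
def cohort_spec() -> CohortSpec:
    return small_cohort_spec()
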