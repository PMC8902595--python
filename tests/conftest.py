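import pytest
from hypothesis import HealthCheck, settings

import morphomark as mm

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas16():
    """16^3 toy parcellation with 8 contiguous regions."""
    return mm.make_atlas((16, 16, 16), 8, seed=7)


@pytest.fixture(scope="session")
def null_cohort(atlas16):
    """Single-site cohort with no group effect (30 + 30 subjects)."""
    design = mm.CohortDesign(n_per_group_per_site={"GU": (30, 30)},
                             effect_size_d=0.0, site_shift_sd=0.0, seed=21)
    return mm.simulate_cohort(design, atlas16)


@pytest.fixture(scope="session")
def effect_cohort(atlas16):
    """Cohort with a strong (d = 3) volume reduction in region 3."""
    design = mm.CohortDesign(n_per_group_per_site={"GU": (30, 30)},
                             effect_regions=(3,), effect_size_d=3.0,
                             site_shift_sd=0.0, seed=22)
    return mm.simulate_cohort(design, atlas16)


@pytest.fixture(scope="session")
def null_mask(null_cohort):
    return mm.build_group_mask(null_cohort, 0.1)
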