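import pytest
from hypothesis import HealthCheck, settings

import betakin as bk
from betakin.pipeline import make_fixtures

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_pedigree() -> bk.Pedigree:
    """The study cohort layout: 100 families, 210 siblings."""
    return bk.make_pedigree()


@pytest.fixture(scope="session")
def toy_bundle() -> dict:
    """Small deterministic fixture bundle (pedigree, envelope, phenotypes)."""
    return make_fixtures(seed=0)
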