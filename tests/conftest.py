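import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from fhdx.config import default_config
from fhdx.io import packaged_reconstruction_cohort, packaged_variant_table
from fhdx.models import LipidPanel, Subject


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def variant_table():
    return packaged_variant_table()


@pytest.fixture(scope="session")
def adult_cohort():
    """The shipped synthetic 31-adult reconstruction cohort."""
    return packaged_reconstruction_cohort()


@pytest.fixture
def make_subject():
    def _make(ldl=None, tc=None, age=40, **kwargs):
        pre = None
        if ldl is not None or tc is not None:
            pre = LipidPanel(ldl_c=ldl, total_cholesterol=tc, is_pretreatment=True)
        return Subject(id="t", age_years=age, pretreatment_lipids=pre, **kwargs)

    return _make
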