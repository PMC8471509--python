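import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dustbox import DustinessRecord, EmissionSpec, Scenario, load_fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    return load_fixtures()


@pytest.fixture()
def clay1_cd_inhalable(bundle):
    """Highest-throughput filling case: DI 1733 mg/kg, 800 kg/min, 70%/70% controls."""
    return bundle.emission_spec("Clay 1", "CD", "inhalable")


@pytest.fixture()
def scenario_l(bundle):
    return bundle.scenarios["L"]


@pytest.fixture()
def simple_record():
    return DustinessRecord(
        material="test powder", method="CD", w_inhalable=1000.0, w_respirable=50.0
    )


@pytest.fixture()
def simple_spec(simple_record):
    return EmissionSpec(
        dustiness=simple_record,
        fraction="respirable",
        h=1.0,
        mass_flow_kg_min=10.0,
        lc_bag_retained=0.5,
        lc_lev_retained=0.5,
    )


@pytest.fixture()
def small_room():
    return Scenario(
        name="small", v=100.0, v_nf=4.0, q_gv=20.0, q_lev=5.0, q_lev_nf=2.0,
        beta=5.0, c0=0.0,
    )
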