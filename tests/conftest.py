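import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from epichart import fixtures as fx
from epichart.hl7 import OrderRecord, PersonName
from epichart.hl7.dialect import allscripts_profile, cerner_profile
from epichart.rbac import Role, User, default_policy
from epichart.workflow import ReportService

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mini_ont():
    return fx.mini_ontology()


@pytest.fixture(scope="session")
def policy():
    return default_policy()


@pytest.fixture
def technician():
    return User("tech1", "Terry Tech", frozenset({Role.EEG_TECHNICIAN}))


@pytest.fixture
def fellow():
    return User("fel1", "Finn Fellow", frozenset({Role.CLINICAL_FELLOW}))


@pytest.fixture
def attending():
    return User("att1", "Avery Attending", frozenset({Role.ATTENDING_PHYSICIAN}))


@pytest.fixture
def navigator():
    return User("nav1", "Noa Navigator", frozenset({Role.NURSE_NAVIGATOR}))


@pytest.fixture
def admin():
    return User("adm1", "Ada Admin", frozenset({Role.ADMIN}))


@pytest.fixture
def profiles():
    return {"allscripts": allscripts_profile(), "cerner": cerner_profile()}


@pytest.fixture
def service(mini_ont):
    return ReportService(ontology=mini_ont)


def make_order(
    mrn="MRN00042",
    placer="PL0001",
    procedure="EEG",
    vendor="cerner",
    when=dt.datetime(2020, 3, 15, 9, 30),
) -> OrderRecord:
    return OrderRecord(
        mrn=mrn,
        patient_name=PersonName("DOE", "JANE"),
        dob=dt.date(1980, 6, 1),
        sex="F",
        placer_id=placer,
        filler_id="FL" + placer[2:],
        procedure_code=procedure,
        procedure_text="Electroencephalogram" if procedure == "EEG" else procedure,
        ordering_provider="DRFOX",
        order_datetime=when,
        source_vendor=vendor,
    )


@pytest.fixture
def sample_order():
    return make_order()
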