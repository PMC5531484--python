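import pytest

from vippanel import fixtures
from vippanel.synth import SimulationParams
from vippanel.validation import build_table2_bundle


@pytest.fixture(scope="session")
def vip1():
    return fixtures.vip1_panel()


@pytest.fixture(scope="session")
def vip2():
    return fixtures.vip2_panel()


@pytest.fixture(scope="session")
def truth():
    return fixtures.load_positive_controls()


@pytest.fixture(scope="session")
def blinded_truth(truth):
    return [r for r in truth if r.patient_id in fixtures.BLINDED_VALIDATION_PATIENTS]


@pytest.fixture(scope="session")
def cohort():
    return fixtures.load_prospective_cohort()


@pytest.fixture(scope="session")
def table2_bundle():
    return build_table2_bundle(SimulationParams(seed=1))
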