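import pytest

from microcyte.cohort import PatientRecord
from microcyte.indices import builtin_registry
from microcyte.synthetic_data import SimulationConfig, generate_cohort


def make_record(**overrides) -> PatientRecord:
    """A mid-range microcytic panel; override fields per test."""
    base = dict(
        hb=10.0, hct=32.0, mcv=70.0, mch=22.0, mchc=31.0, rbc=5.0,
        rdw=15.0, hba2=4.0, ferritin=80.0, sex="female",
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient synthetic cohort, fixed seed, default group geometry."""
    return generate_cohort(SimulationConfig(n_btt=120, n_ida=80, seed=42))
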