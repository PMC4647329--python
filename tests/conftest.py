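import pytest
from hypothesis import settings

from strokescale.cohort import CohortTable, PatientRecord

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")
from strokescale.simulate import default_params, generate_cohort

PANEL = ("anxiety", "irritability", "circumrotating", "tinnitus")


def make_record(
    rid="p1",
    age=60.0,
    sex="male",
    dm=False,
    nihss_d1=4,
    nihss_d3=4,
    bi=95,
    sym_d1=(),
    sym_d3=(),
    onset=6.0,
):
    """Handmade record over the 4-symptom test panel."""
    history = {"hypertension": False, "stroke": False, "chd": False, "dm": dm, "af": False}
    return PatientRecord(
        id=rid,
        age=age,
        sex=sex,
        history=history,
        onset_to_admission=onset,
        nihss_day1=nihss_d1,
        nihss_day3=nihss_d3,
        symptoms_day1={s: s in sym_d1 for s in PANEL},
        symptoms_day3={s: s in sym_d3 for s in PANEL},
        bi_day90=bi,
    )


@pytest.fixture
def tiny_cohort():
    records = (
        make_record("a", age=70, dm=True, nihss_d1=9, nihss_d3=10, bi=40,
                    sym_d1=("anxiety",), sym_d3=("anxiety", "tinnitus")),
        make_record("b", age=50, nihss_d1=2, nihss_d3=1, bi=95,
                    sym_d1=("circumrotating",), sym_d3=()),
        make_record("c", age=61, sex="female", nihss_d1=5, nihss_d3=5, bi=90),
    )
    return CohortTable(records=records, panel=PANEL)


@pytest.fixture(scope="session")
def synthetic_cohort_413():
    """One derivation-sized synthetic cohort, shared across tests."""
    return generate_cohort(default_params(n=413, seed=20251001))
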