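import numpy as np
import pandas as pd
import pytest

from riskconcord.cohort import ParticipantRecord
from riskconcord.engines import MODEL_ORDER
from riskconcord.synthetic import default_config_from_table1, generate_cohort

_BASE = dict(
    sbp=135.0, dbp=85.0, waist=100.0, bmi=31.0, tc=6.0, ldl=3.8, hdl=1.2,
    tg=1.9, glucose=5.8, creatinine=75.0, egfr=92.0, crp=2.5,
    smoking="never", diabetes=False, htn_dx=False, htn_treated=False,
    lipid_treated=False, antiplatelet=False, family_history_premature_cvd=False,
)


@pytest.fixture
def make_record():
    """Factory for valid participant records with overridable fields."""

    def _make(id="p1", sex="female", age=55.0, **overrides):
        fields = dict(_BASE, id=id, sex=sex, age=age)
        fields.update(overrides)
        return ParticipantRecord(**fields)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 300-record synthetic cohort shared across tests."""
    return generate_cohort(default_config_from_table1(n=300, seed=11))


@pytest.fixture(scope="session")
def cohort_5000():
    """The parameter-recovery-scale cohort (n=5000, fixed seed)."""
    return generate_cohort(default_config_from_table1(n=5000, seed=2024))


@pytest.fixture
def random_decisions():
    """Factory for seeded random n x 9 boolean decision frames."""

    def _make(n=50, seed=0, p=0.4):
        rng = np.random.default_rng(seed)
        data = rng.random((n, len(MODEL_ORDER))) < p
        return pd.DataFrame(data, columns=list(MODEL_ORDER),
                            index=[f"r{i}" for i in range(n)])

    return _make
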