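import numpy as np
import pytest
from hypothesis import settings

import pvmarkov as pv

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def life_table():
    """The shipped synthetic Gompertz–Makeham life table."""
    return pv.synthesize_life_table()


@pytest.fixture(scope="session")
def immortal_table():
    """All-zero mortality table covering ages 0-110 (qx forced open)."""
    ages = np.arange(0, 111)
    return pv.LifeTable(ages=ages, qx=np.zeros(ages.size), source="immortal")


@pytest.fixture(scope="session")
def base_config(life_table):
    return pv.base_case_config(life_table=life_table)


@pytest.fixture(scope="session")
def zero_risks():
    return pv.RiskSet(
        p_thrombosis_low=0.0,
        p_thrombosis_high=0.0,
        p_al=0.0,
        p_mf_low=0.0,
        p_mf_high=0.0,
        m_thrombosis=0.0,
        m_al=0.0,
        m_mf=0.0,
    )
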