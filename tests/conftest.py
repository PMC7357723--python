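import datetime

import pytest

from ssnmrice import (
    Establishment,
    FieldInterview,
    IrrigationSource,
    ResidueManagement,
    Season,
    VarietyInfo,
    default_params,
    product_catalog_default,
)


@pytest.fixture
def catalog():
    return product_catalog_default()


@pytest.fixture
def kuruvai_params():
    return default_params(Season.KURUVAI)


@pytest.fixture
def samba_params():
    return default_params(Season.SAMBA)


@pytest.fixture
def thaladi_params():
    return default_params(Season.THALADI)


def make_interview(**overrides) -> FieldInterview:
    """A valid transplanted-kuruvai interview; keyword overrides per test."""
    base = dict(
        field_id="f1",
        field_area=1.0,
        season=Season.KURUVAI,
        irrigation_source=IrrigationSource.TUBE_WELL,
        variety=VarietyInfo(name="ADT 43", duration=110,
                            baseline_yield_lo=4.6, baseline_yield_hi=6.1),
        establishment=Establishment.TRANSPLANTED,
        seedling_age=25,
        sowing_date=datetime.date(2014, 6, 10),
        establishment_date=datetime.date(2014, 7, 5),
        historical_yield=4.8,
        prev_residue=ResidueManagement.REMOVED,
        selected_products=["dap", "muriate_of_potash"],
    )
    base.update(overrides)
    return FieldInterview(**base)


@pytest.fixture
def interview():
    return make_interview()
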