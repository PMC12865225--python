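"""Shared fixtures: study-design concentration series and reference values."""

import pytest

from transporter_ddi.static_risk import PrecipitantProfile

# 7-point inhibitor series (half-log spacing) as used in the cell assays
INHIBITOR_CONCS = [0.41, 1.23, 3.7, 11.1, 33.3, 100.0, 300.0]
# wider series for the weaker (vesicle) inhibitions
VESICLE_CONCS = [4.1, 12.3, 37.0, 111.0, 333.0, 1000.0, 3000.0]

# In vitro IC50s (uM) for the two isoxazolyl penicillins; P-gp for
# flucloxacillin is a lower bound.
IC50_DICLOXACILLIN = {
    "OATP1B1": 3.86,
    "OATP1B3": 6.68,
    "OATP2B1": 35.5,
    "OAT3": 19.5,
    "OAT4": 7.23,
    "BCRP": 166.0,
    "P-gp": 258.0,
}
IC50_FLUCLOXACILLIN = {
    "OATP1B1": 30.7,
    "OATP1B3": 20.7,
    "OATP2B1": 64.2,
    "OAT3": 26.6,
    "OAT4": 32.7,
    "BCRP": 379.0,
    "P-gp": (833.0, "lower_bound"),
}


@pytest.fixture
def dicloxacillin_profile() -> PrecipitantProfile:
    return PrecipitantProfile(
        name="dicloxacillin", fu_p=0.02, cmax_total=67.0, dose_mg=1000.0,
        mw=470.33, fa=1.0, fg=1.0, ka=0.1, qh=1.62, rb=0.65,
    )


@pytest.fixture
def flucloxacillin_profile() -> PrecipitantProfile:
    return PrecipitantProfile(
        name="flucloxacillin", fu_p=0.06, cmax_total=46.0, dose_mg=1000.0,
        mw=453.87, fa=1.0, fg=1.0, ka=0.1, qh=1.62, rb=0.65,
    )
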