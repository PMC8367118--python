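import pytest

from needspend.population import AgeSexBand, PopulationProfile
from needspend.synthetic import RegionConfig, generate_coefficients, generate_region
from needspend.weighting import CoefficientTable

# one all-ages band per sex: the smallest banding that satisfies coverage
FEMALE_ALL = AgeSexBand("female", 0, None)
MALE_ALL = AgeSexBand("male", 0, None)


def two_band_profile(female: float, male: float) -> PopulationProfile:
    return PopulationProfile({FEMALE_ALL: female, MALE_ALL: male})


def toy_core_table(
    needs=(1.0, 1.0),
    local_factors=None,
    scheme: str = "core_services",
    weights=None,
) -> CoefficientTable:
    """A minimal single-component core-style table over the 2-band toy
    banding; needs = (female, male) general & acute multipliers."""
    bands = (FEMALE_ALL, MALE_ALL)
    shares = {FEMALE_ALL: 0.5, MALE_ALL: 0.5}
    need = {FEMALE_ALL: needs[0], MALE_ALL: needs[1]}
    weights = weights or {"general_acute": 1.0}
    table = CoefficientTable(
        scheme=scheme,
        bands=bands,
        reference_mean=sum(shares[b] * need[b] for b in bands),
        reference_shares=shares,
        component_weights=weights,
        component_need={c: dict(need) for c in weights},
        local_factors=local_factors or {"A": {"utilization": 1.0}},
    )
    table.validate()
    return table


def toy_carr_hill_table(needs=(1.0, 1.0), local_factors=None, premium=0.0):
    bands = (FEMALE_ALL, MALE_ALL)
    shares = {FEMALE_ALL: 0.5, MALE_ALL: 0.5}
    need = {FEMALE_ALL: needs[0], MALE_ALL: needs[1]}
    table = CoefficientTable(
        scheme="carr_hill",
        bands=bands,
        reference_mean=sum(shares[b] * need[b] for b in bands),
        reference_shares=shares,
        band_need=need,
        nursing_home_premium=premium,
        local_factors=local_factors or {"A": {"mortality": 1.0}},
    )
    table.validate()
    return table


@pytest.fixture(scope="session")
def synthetic_tables():
    return generate_coefficients(seed=5)


@pytest.fixture(scope="session")
def desk_region():
    return generate_region(RegionConfig.desk_scale(seed=11))
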