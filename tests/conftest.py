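import pytest

from noxtrace import FractionationEstimate, SourceSignature

# end-member set used across tests: coal and microbial carry their published
# signatures; vehicle and biomass values are synthetic but well separated
SOURCE_PARAMS = {
    "coal_combustion": (13.7, 3.9),
    "vehicle_exhaust": (-4.0, 3.0),
    "biomass_burning": (1.0, 4.0),
    "microbial_N": (-30.2, 6.7),
}


@pytest.fixture(scope="session")
def sources4() -> list[SourceSignature]:
    return [SourceSignature(n, m, s) for n, (m, s) in SOURCE_PARAMS.items()]


@pytest.fixture(scope="session")
def sources3(sources4) -> list[SourceSignature]:
    return [s for s in sources4 if s.name != "vehicle_exhaust"]


@pytest.fixture(scope="session")
def offset_pooled() -> FractionationEstimate:
    return FractionationEstimate(3.9, 1.8, "pooled")
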