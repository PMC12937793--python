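import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from padflow import REFERENCE_VESSEL, StenosisSpec, VesselSegment


@pytest.fixture
def vessel() -> VesselSegment:
    """The reference epicardial segment (l=30 mm, r0=1.5 mm)."""
    return REFERENCE_VESSEL


@pytest.fixture
def spec50(vessel) -> StenosisSpec:
    return StenosisSpec(sigma=0.5, throat_length_Ls=5e-3, vessel=vessel)
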