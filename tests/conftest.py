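import numpy as np
import pytest

from relkin.model import TransportParams
from relkin.pipeline import tablet_protocol, trim_protocol
from relkin.synthetic import reference_profiles

# Every percentage the packaged fixtures are allowed to contain, keyed by
# (formulation, time in hours).  Frozen here independently of the CSV.
PRINTED_PCT = {
    ("K-1 F-1", 2): 37.8, ("K-1 F-1", 5): 60.2, ("K-1 F-1", 7): 68.3,
    ("K-1 F-1", 9): 74.9, ("K-1 F-1", 11): 77.3,
    ("K-2 F-2", 2): 48.2, ("K-2 F-2", 5): 74.3, ("K-2 F-2", 7): 81.6,
    ("K-2 F-2", 9): 87.5, ("K-2 F-2", 11): 88.6,
    ("K-3 F-3", 2): 60.5, ("K-3 F-3", 5): 88.1, ("K-3 F-3", 7): 96.2,
    ("K-3 F-3", 9): 98.7, ("K-3 F-3", 11): 99.1,
    ("K-1 F-4", 2): 32.4, ("K-1 F-4", 5): 56.1, ("K-1 F-4", 7): 65.8,
    ("K-1 F-4", 9): 67.33, ("K-1 F-4", 12): 76.6,
    ("K-2 F-5", 2): 41.2, ("K-2 F-5", 5): 67.6, ("K-2 F-5", 7): 79.1,
    ("K-2 F-5", 9): 84.5, ("K-2 F-5", 12): 86.3,
    ("K-3 F-6", 2): 54.3, ("K-3 F-6", 5): 87.9, ("K-3 F-6", 7): 95.2,
    ("K-3 F-6", 9): 97.1, ("K-3 F-6", 12): 97.5,
}

# Drug content per tablet: 70 mg free drug; complex tablets carry 150 mg of
# complex, of which the guest mass fraction is drug.
DRUG_CONTENT_MG = {
    "K-1": 70.0,
    "K-2": 150.0 * 0.3094293256239506,   # 2:1 complex
    "K-3": 150.0 * 0.18303246963523356,  # 1:1 complex
}


def drug_content_for(formulation_id: str) -> float:
    return DRUG_CONTENT_MG[formulation_id.split()[0]]


@pytest.fixture(scope="session")
def fixtures():
    return reference_profiles()


@pytest.fixture(scope="session")
def protocol12():
    return tablet_protocol()


@pytest.fixture
def protocol_for():
    def _make(profile):
        return trim_protocol(tablet_protocol(), float(profile.times_h[-1]))
    return _make


@pytest.fixture
def drift_params():
    return TransportParams(V=1.0, D=1.0, rho0=1.0)


@pytest.fixture
def diffusion_params():
    return TransportParams(V=0.0, D=1.0, rho0=1.0)
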