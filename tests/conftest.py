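import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from wepcast import AcquisitionProtocol, PhysioParams


@pytest.fixture(scope="session")
def protocol():
    """Default tau=4 s / PLD=3 s protocol with the (1600, 2900) ms bs pair."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def no_bs_protocol():
    return AcquisitionProtocol(bs_times=())


@pytest.fixture(scope="session")
def physio():
    """Default physiology (female blood T1, CBF 55 mL/100 g/min)."""
    return PhysioParams()


@pytest.fixture(scope="session")
def physio_male():
    return PhysioParams(t1_blood=1667.0)
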