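import pytest

from arddpcr.assays import builtin_assay
from arddpcr.gating import derive_gates
from arddpcr.simulate import AmplitudeModel, simulate_controls


@pytest.fixture(scope="session")
def amp1():
    return builtin_assay("AR-Amp-1/T877A")


@pytest.fixture(scope="session")
def amp2():
    return builtin_assay("AR-Amp-2")


@pytest.fixture(scope="session")
def model():
    return AmplitudeModel()


@pytest.fixture(scope="session")
def gates1(amp1, model):
    return derive_gates(simulate_controls(amp1, seed=101, model=model), amp1)


@pytest.fixture(scope="session")
def gates2(amp2, model):
    return derive_gates(simulate_controls(amp2, seed=202, model=model), amp2)
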