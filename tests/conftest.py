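import pytest

from careoptions import ScenarioParams, clhls_waves


@pytest.fixture(scope="session")
def baseline() -> ScenarioParams:
    """The baseline 300-bed scenario (Table-1-style defaults)."""
    return ScenarioParams()


@pytest.fixture(scope="session")
def reference(baseline) -> ScenarioParams:
    """Low-uncertainty reference group: alpha=0.001, sigma=0.06."""
    return baseline.replace(alpha=0.001, sigma=0.06)


@pytest.fixture(scope="session")
def survey_waves():
    """The packaged eight-wave CLHLS nursing-home proportion series."""
    return clhls_waves()
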