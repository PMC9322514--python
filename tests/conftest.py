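import pytest

from felopbpk import build_protocol, simulate


@pytest.fixture(scope="session")
def solution_profile():
    """10 mg oral solution in the default individual, 48 h."""
    return simulate(build_protocol("solution", 10.0, output_grid=10.0))


@pytest.fixture(scope="session")
def iv_profile():
    """1 mg intravenous infusion (10 min) in the default individual, 48 h."""
    return simulate(build_protocol("iv", 1.0, output_grid=10.0))


@pytest.fixture(scope="session")
def taber_profile():
    """10 mg extended-release tablet in the default individual, 48 h."""
    return simulate(build_protocol("tabER", 10.0, output_grid=10.0))
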