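import pytest

from lacflux.config import oxidative_reference
from lacflux.steady_state import solve_steady_state


@pytest.fixture(scope="session")
def reference():
    """The bundled calibrated oxidative-cell config."""
    return oxidative_reference()


@pytest.fixture(scope="session")
def params(reference):
    return reference.parameters


@pytest.fixture(scope="session")
def env(reference):
    return reference.environment


@pytest.fixture(scope="session")
def options(reference):
    return reference.options


@pytest.fixture(scope="session")
def constraints(reference):
    return reference.constraints


@pytest.fixture(scope="session")
def basal(reference):
    """Solved basal steady state of the reference oxidative cell."""
    return solve_steady_state(reference.parameters, reference.environment,
                              reference.options)
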