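import pytest

from adpa_circuit.circuit import CircuitParams
from adpa_circuit.synthetic import synthetic_adpa_standin


@pytest.fixture(scope="session")
def default_params() -> CircuitParams:
    return CircuitParams()


@pytest.fixture(scope="session")
def standin_protein():
    """Synthetic AdpA-like protein (Cys at 62/89/113/137)."""
    return synthetic_adpa_standin()
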