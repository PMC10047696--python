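import numpy as np
import pytest

import qphi as q

AB = ("A", "B")
ABC = ("A", "B", "C")

COPY_XOR_TABLE = {"00": "00", "01": "01", "10": "11", "11": "10"}


@pytest.fixture(scope="session")
def cnot():
    return q.named_gate("CNOT", AB)


@pytest.fixture(scope="session")
def copy_xor_tpm():
    return q.TPM.from_truth_table(COPY_XOR_TABLE, ("A", "B"), ("C", "D"))


@pytest.fixture
def rng():
    return np.random.default_rng(20230303)


def state(spec, units=AB):
    return q.parse_state(spec, units)


def mech(rho, units):
    return q.Mechanism.from_system(rho, units)
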