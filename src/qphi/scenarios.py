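"""Canonical analysis scenarios and randomized instance generators.

The named scenarios cover the canonical CNOT analyses (computational and
Hadamard-basis inputs, Bell-state creation, a classically correlated mixed
input), the three-qubit extension of the CNOT by an identity wire, and the
identity-channel constraint analyses of the GHZ and W states.  Each builds a
ready-to-run unfolding job.  Random instances (Haar unitaries, permutation
gates, product / random mixed states) back the property-test suites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from . import channels as ch
from .analysis import Unfolding, unfold
from .qstate import LabeledState, StateError, parse_state


@dataclass(frozen=True)
class Scenario:
    """A fully specified analysis job: register, state, channel, mode."""

    name: str
    units: tuple[str, ...]
    state: object  # parse_state spec
    channel: object  # gate name, truth table or explicit matrix
    mode: str = "transition"
    description: str = ""
    output_units: tuple[str, ...] = field(default=())

    def build(self) -> tuple[ch.UnitaryChannel | None, LabeledState]:
        rho = parse_state(self.state, self.units)
        chan = self.channel
        if chan is None:
            return None, rho
        if isinstance(chan, ch.UnitaryChannel):
            return chan, rho
        if isinstance(chan, str):
            return ch.named_gate(chan, self.units), rho
        if isinstance(chan, Mapping):
            if all(isinstance(v, str) for v in chan.values()):
                return ch.from_truth_table(chan, self.units), rho
            raise StateError("channel mapping must be a truth table")
        return ch.UnitaryChannel(self.units, np.asarray(chan, dtype=complex)), rho

    def run(self) -> Unfolding:
        T, rho = self.build()
        return unfold(T, rho, self.mode)


_AB = ("A", "B")
_ABC = ("A", "B", "C")

SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario(
            "cnot_10", _AB, "10", "CNOT",
            description="CNOT on the computational input 10 (classical regime: "
            "control copied, target XOR); converges to the COPY-XOR analysis.",
            output_units=("C", "D"),
        ),
        Scenario(
            "cnot_minus_plus", _AB, "-+", "CNOT",
            description="CNOT on the Hadamard-basis input -+; control and "
            "target roles reverse.",
        ),
        Scenario(
            "cnot_bell", _AB, "+0", "CNOT",
            description="Bell-state creation: CNOT on +0; only second-order "
            "mechanisms carry information.",
        ),
        Scenario(
            "cnot_0plus", _AB, "0+", "CNOT",
            description="CNOT on 0+; no interaction, only first-order "
            "mechanisms.",
        ),
        Scenario(
            "cnot_mixture", _AB, {"00": 0.5, "11": 0.5}, "CNOT",
            description="CNOT on the even classical mixture of 00 and 11.",
        ),
        Scenario(
            "extended_cnot_ghz", _ABC, "ghz", "I⊗CNOT",
            description="CNOT extended by an identity wire, applied to a GHZ "
            "state: the two-qubit mixed-state analysis embedded in a "
            "three-qubit system.",
        ),
        Scenario(
            "ghz_self", _ABC, "ghz", None, mode="self",
            description="Constraint analysis of the GHZ state under the "
            "identity channel: a single third-order constraint.",
        ),
        Scenario(
            "w_self", _ABC, "w", None, mode="self",
            description="Constraint analysis of the W state: constraints at "
            "all orders.",
        ),
        Scenario(
            "classical_000_self", _ABC, "000", None, mode="self",
            description="Constraint analysis of a classical basis state: "
            "first-order constraints only.",
        ),
    ]
}


def load_scenario(name_or_path: str) -> Scenario:
    """Look up a named scenario or load one from a YAML/JSON file."""
    if name_or_path in SCENARIOS:
        return SCENARIOS[name_or_path]
    try:
        with open(name_or_path) as fh:
            cfg = yaml.safe_load(fh)
    except OSError as e:
        raise StateError(
            f"{name_or_path!r} is neither a known scenario "
            f"({', '.join(sorted(SCENARIOS))}) nor a readable file: {e}"
        ) from e
    try:
        return Scenario(
            name=cfg.get("name", name_or_path),
            units=tuple(cfg["register"]),
            state=cfg["state"],
            channel=cfg.get("channel"),
            mode=cfg.get("mode", "transition"),
            description=cfg.get("description", ""),
        )
    except KeyError as e:
        raise StateError(f"scenario file {name_or_path} is missing key {e}") from e


# ---------------------------------------------------------------------------
# Randomized instances
# ---------------------------------------------------------------------------


def haar_unitary(rng: np.random.Generator, dim: int) -> np.ndarray:
    """Haar-distributed unitary via QR of a complex Gaussian matrix."""
    z = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    q, r = np.linalg.qr(z)
    return q * (np.diag(r) / np.abs(np.diag(r)))


def random_permutation_table(rng: np.random.Generator, n: int) -> dict[str, str]:
    perm = rng.permutation(2**n)
    return {format(i, f"0{n}b"): format(int(p), f"0{n}b")
            for i, p in enumerate(perm)}


def random_density_matrix(rng: np.random.Generator, dim: int,
                          pure: bool = False) -> np.ndarray:
    if pure:
        v = rng.normal(size=dim) + 1j * rng.normal(size=dim)
        v /= np.linalg.norm(v)
        return np.outer(v, v.conj())
    evals = rng.dirichlet(np.ones(dim))
    U = haar_unitary(rng, dim)
    return (U * evals) @ U.conj().T


def random_instance(seed: int, n_qubits: int = 2, kind: str = "haar_unitary") -> Scenario:
    """A reproducible random scenario of the requested kind.

    Kinds: ``haar_unitary`` (Haar channel on a random product state),
    ``permutation`` (reversible classical gate on a random basis state),
    ``product_state`` (identity channel, random pure product state),
    ``random_mixed`` (identity channel, random full-rank mixed state).
    """
    if n_qubits not in (2, 3):
        raise StateError("random_instance supports 2 or 3 qubits")
    rng = np.random.default_rng(seed)
    units = tuple("ABC"[:n_qubits])
    dim = 2**n_qubits
    if kind == "haar_unitary":
        channel = ch.UnitaryChannel(units, haar_unitary(rng, dim))
        state = _random_product(rng, n_qubits)
        return Scenario(f"haar_{seed}", units, state, channel)
    if kind == "permutation":
        table = random_permutation_table(rng, n_qubits)
        basis = format(rng.integers(dim), f"0{n_qubits}b")
        return Scenario(f"perm_{seed}", units, basis, table)
    if kind == "product_state":
        return Scenario(f"prod_{seed}", units, _random_product(rng, n_qubits),
                        None, mode="self")
    if kind == "random_mixed":
        return Scenario(f"mixed_{seed}", units,
                        random_density_matrix(rng, dim), None, mode="self")
    raise StateError(f"unknown random instance kind {kind!r}")


def _random_product(rng: np.random.Generator, n: int) -> np.ndarray:
    m = np.ones((1, 1), dtype=complex)
    for _ in range(n):
        m = np.kron(m, random_density_matrix(rng, 2, pure=True))
    return m
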