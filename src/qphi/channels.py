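"""Unitary dynamics: gate library, application, adjoint, classical embeddings.

Only unitary channels are executable.  General CPTP (Kraus) maps can be
represented by :class:`KrausChannel` for bookkeeping, but applying one raises
an explicit error: the backward (cause) analysis is defined only for
unitaries, where the inverse equals the adjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .qstate import TOL, LabeledState, StateError


class ChannelError(ValueError):
    """Raised for invalid channel specifications or applications."""


class UnsupportedDynamicsError(ChannelError):
    """Raised when a non-unitary channel is asked to act."""


@dataclass(frozen=True)
class UnitaryChannel:
    """A unitary matrix acting on a full register of qubit units."""

    units: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        u = np.asarray(self.matrix, dtype=complex)
        d = 2 ** len(self.units)
        if u.shape != (d, d):
            raise ChannelError(
                f"unitary shape {u.shape} does not match register {self.units}"
            )
        if np.abs(u.conj().T @ u - np.eye(d)).max() > 1e3 * TOL:
            raise ChannelError("matrix is not unitary within tolerance")
        object.__setattr__(self, "matrix", u)

    @property
    def dim(self) -> int:
        return 2 ** len(self.units)

    def adjoint(self) -> "UnitaryChannel":
        return UnitaryChannel(self.units, self.matrix.conj().T)

    def to_json(self) -> dict:
        return {
            "units": list(self.units),
            "matrix": [
                [[float(z.real), float(z.imag)] for z in row] for row in self.matrix
            ],
        }


@dataclass(frozen=True)
class KrausChannel:
    """A general CPTP map, represented but not executable.

    Kept in the data model so configurations can describe non-unitary
    dynamics; the causal analysis rejects them because the cause-side
    computation requires the channel inverse to equal the adjoint.
    """

    units: tuple[str, ...]
    operators: tuple[np.ndarray, ...]


def apply(U: UnitaryChannel, rho: LabeledState) -> LabeledState:
    """Forward action U rho U^dagger (trace and positivity preserving)."""
    if isinstance(U, KrausChannel):
        raise UnsupportedDynamicsError("unsupported: non-unitary dynamics")
    if rho.units != U.units:
        if set(rho.units) != set(U.units):
            raise ChannelError(
                f"state register {rho.units} does not span channel register {U.units}"
            )
        rho = rho.reorder(U.units)
    return LabeledState(U.units, U.matrix @ rho.matrix @ U.matrix.conj().T)


def apply_adjoint(U: UnitaryChannel, rho: LabeledState) -> LabeledState:
    """Backward action U^dagger rho U, used for cause repertoires."""
    return apply(U.adjoint(), rho)


# ---------------------------------------------------------------------------
# Gate library
# ---------------------------------------------------------------------------

_CNOT = np.array(
    [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float
)
_SWAP = np.array(
    [[1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 1]], dtype=float
)
_H = np.array([[1, 1], [1, -1]], dtype=float) / np.sqrt(2.0)

#: Basic named gates and the number of qubits each acts on.  For CNOT the
#: control is the first unit of the pair (10 -> 11 in the computational basis).
_BASIC_GATES: dict[str, np.ndarray] = {
    "I": np.eye(2),
    "X": np.array([[0, 1], [1, 0]], dtype=float),
    "Y": np.array([[0, -1j], [1j, 0]]),
    "Z": np.diag([1.0, -1.0]),
    "H": _H,
    "CNOT": _CNOT,
    "SWAP": _SWAP,
}


def named_gate(name: str, units: Sequence[str]) -> UnitaryChannel:
    """Build a standard gate by name on the given register.

    Tensor expressions are accepted with a separator, e.g. ``"I⊗CNOT"`` (or
    the ASCII form ``"I@CNOT"``) on a three-unit register extends the CNOT by
    an identity on the first unit.
    """
    units = tuple(units)
    expr = name.replace("⊗", "@").replace("*", "@")
    factors = [f.strip().upper() for f in expr.split("@")]
    mats = []
    n_needed = 0
    for f in factors:
        if f not in _BASIC_GATES:
            raise ChannelError(f"unknown gate name {f!r} in {name!r}")
        g = _BASIC_GATES[f]
        mats.append(g)
        n_needed += int(np.log2(g.shape[0]))
    if n_needed != len(units):
        raise ChannelError(
            f"gate {name!r} acts on {n_needed} qubits, register {units} has "
            f"{len(units)}"
        )
    m = mats[0]
    for g in mats[1:]:
        m = np.kron(m, g)
    return UnitaryChannel(units, m)


def from_truth_table(
    table: Mapping[str, str], units: Sequence[str] | None = None
) -> UnitaryChannel:
    """Permutation unitary embedding a reversible classical gate.

    ``table`` maps input bit-strings to output bit-strings (a bijection on
    {0,1}^n, strings read in register order).  The result has
    ``P[out, in] = 1``.
    """
    if not table:
        raise ChannelError("empty truth table")
    n = len(next(iter(table)))
    if len(table) != 2**n or any(len(k) != n or len(v) != n for k, v in table.items()):
        raise ChannelError("truth table must cover all n-bit inputs")
    outs = set(table.values())
    if len(outs) != 2**n:
        raise ChannelError("irreversible truth table: outputs are not a bijection")
    if units is None:
        units = tuple("ABCDEFGH"[:n])
    P = np.zeros((2**n, 2**n))
    for k, v in table.items():
        P[int(v, 2), int(k, 2)] = 1.0
    return UnitaryChannel(tuple(units), P)


def as_truth_table(U: UnitaryChannel, tol: float = TOL) -> dict[str, str] | None:
    """Inverse of :func:`from_truth_table`; None if U is not a permutation."""
    d = U.dim
    n = len(U.units)
    table: dict[str, str] = {}
    for col in range(d):
        column = U.matrix[:, col]
        ones = np.flatnonzero(np.abs(column - 1.0) < tol)
        if len(ones) != 1 or np.abs(column).sum() - 1.0 > tol:
            return None
        table[format(col, f"0{n}b")] = format(int(ones[0]), f"0{n}b")
    return table
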