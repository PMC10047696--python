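"""Density-matrix core: labeled qubit registers and the operations on them.

A register is an ordered tuple of short unit names (``("A", "B")``); the
order defines the tensor-product order, with the leftmost label the leftmost
Kronecker factor.  Basis-state strings are read left to right in register
order, so ``"10"`` on register AB is the basis index ``0b10 = 2``.

States are plain density matrices bound to their register
(:class:`LabeledState`): Hermitian, unit trace, positive semidefinite within
a global numerical tolerance.  All matrix elements of the states treated by
this package are dyadic rationals (or simple surds), so the tolerances only
absorb floating-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Global tolerance for Hermiticity / trace / positivity checks.
TOL = 1e-9
#: Tolerance used to group nearly equal eigenvalues into degenerate groups.
DEG_TOL = 1e-8


class StateError(ValueError):
    """Raised for invalid states, registers or state specifications."""


# ---------------------------------------------------------------------------
# LabeledState
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledState:
    """A density matrix bound to an ordered subset of named qubit units."""

    units: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        units = tuple(self.units)
        object.__setattr__(self, "units", units)
        if len(set(units)) != len(units):
            raise StateError(f"duplicate unit labels in register {units}")
        m = np.asarray(self.matrix, dtype=complex)
        d = 2 ** len(units)
        if m.shape != (d, d):
            raise StateError(
                f"matrix shape {m.shape} does not match register {units} (dim {d})"
            )
        object.__setattr__(self, "matrix", m)

    # -- basic queries ------------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def dim(self) -> int:
        return 2 ** len(self.units)

    def validate(self, tol: float = TOL) -> "LabeledState":
        """Check Hermiticity, unit trace and positive semidefiniteness."""
        m = self.matrix
        if np.abs(m - m.conj().T).max() > tol:
            raise StateError("state is not Hermitian within tolerance")
        if abs(np.trace(m).real - 1.0) > 1e3 * tol or abs(np.trace(m).imag) > tol:
            raise StateError(f"state trace {np.trace(m)} is not 1 within tolerance")
        evals = np.linalg.eigvalsh(m)
        if evals.min() < -1e3 * tol:
            raise StateError(f"state has negative eigenvalue {evals.min()}")
        return self

    def purity(self) -> float:
        return float(np.trace(self.matrix @ self.matrix).real)

    def reorder(self, new_units: Sequence[str]) -> "LabeledState":
        """Permute the tensor factors so the register reads ``new_units``."""
        new_units = tuple(new_units)
        if set(new_units) != set(self.units) or len(new_units) != len(self.units):
            raise StateError(f"{new_units} is not a permutation of {self.units}")
        if new_units == self.units:
            return self
        n = self.n_units
        perm = [self.units.index(u) for u in new_units]
        t = self.matrix.reshape([2] * (2 * n))
        t = t.transpose(perm + [p + n for p in perm])
        return LabeledState(new_units, t.reshape(self.dim, self.dim))

    def to_json(self) -> dict:
        return {
            "units": list(self.units),
            "matrix": [
                [[float(z.real), float(z.imag)] for z in row] for row in self.matrix
            ],
        }

    @staticmethod
    def from_json(obj: Mapping) -> "LabeledState":
        m = np.array(
            [[complex(re, im) for re, im in row] for row in obj["matrix"]]
        )
        return LabeledState(tuple(obj["units"]), m)


# ---------------------------------------------------------------------------
# Constructors and register algebra
# ---------------------------------------------------------------------------


def compose(states: Sequence[LabeledState]) -> LabeledState:
    """Kronecker-compose states on disjoint registers, in the order given."""
    if not states:
        raise StateError("compose() requires at least one state")
    units: tuple[str, ...] = ()
    for s in states:
        if set(s.units) & set(units):
            raise StateError(
                f"unit label collision composing {s.units} onto {units}"
            )
        units = units + s.units
    m = states[0].matrix
    for s in states[1:]:
        m = np.kron(m, s.matrix)
    return LabeledState(units, m)


def partial_trace(rho: LabeledState, keep: Iterable[str]) -> LabeledState:
    """Reduced density matrix over ``keep``, register order preserved."""
    keep = set(keep)
    if not keep:
        raise StateError("partial_trace: keep must be nonempty")
    if not keep <= set(rho.units):
        raise StateError(f"partial_trace: {keep} is not a subset of {rho.units}")
    kept = tuple(u for u in rho.units if u in keep)
    if kept == rho.units:
        return rho
    n = rho.n_units
    keep_ax = [i for i, u in enumerate(rho.units) if u in keep]
    drop_ax = [i for i, u in enumerate(rho.units) if u not in keep]
    t = rho.matrix.reshape([2] * (2 * n))
    perm = keep_ax + drop_ax
    t = t.transpose(perm + [p + n for p in perm])
    dk, dd = 2 ** len(keep_ax), 2 ** len(drop_ax)
    t = t.reshape(dk, dd, dk, dd)
    return LabeledState(kept, np.einsum("ijkj->ik", t))


def maximally_mixed(units: Iterable[str]) -> LabeledState:
    """The maximally mixed state I / 2^n on ``units`` (register order kept)."""
    units = tuple(units)
    if not units:
        raise StateError("maximally_mixed: units must be nonempty")
    d = 2 ** len(units)
    return LabeledState(units, np.eye(d) / d)


# ---------------------------------------------------------------------------
# Eigendecomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EigenSystem:
    """Eigenvalues (descending) with aligned orthonormal eigenvectors.

    ``groups`` lists index groups of eigenvalues equal within the degeneracy
    tolerance; the basis chosen inside a degenerate group is arbitrary, and
    all downstream quantities are invariant to that choice.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # column i belongs to eigenvalues[i]
    groups: tuple[tuple[int, ...], ...] = field(default=())

    def reconstruct(self) -> np.ndarray:
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.conj().T


def eigendecompose(
    rho: LabeledState, tol: float = TOL, deg_tol: float = DEG_TOL
) -> EigenSystem:
    """Spectral decomposition of a density matrix.

    Eigenvalues are sorted descending; values within ``-tol`` of zero are
    clipped to 0 and the spectrum renormalized to unit sum.  Eigenvalues
    within ``deg_tol`` of each other are flagged as a degenerate group.
    """
    m = rho.matrix
    if np.abs(m - m.conj().T).max() > 1e3 * tol:
        raise StateError("eigendecompose: input is not Hermitian within tolerance")
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    evals = evals[order].real
    evecs = evecs[:, order]
    if evals.min() < -1e3 * tol:
        raise StateError(f"eigendecompose: negative eigenvalue {evals.min()}")
    evals = np.clip(evals, 0.0, None)
    s = evals.sum()
    if s > 0:
        evals = evals / s
    groups: list[tuple[int, ...]] = []
    current = [0]
    for i in range(1, len(evals)):
        if abs(evals[i] - evals[current[-1]]) <= deg_tol:
            current.append(i)
        else:
            groups.append(tuple(current))
            current = [i]
    groups.append(tuple(current))
    return EigenSystem(evals, evecs, tuple(groups))


# ---------------------------------------------------------------------------
# State parsing
# ---------------------------------------------------------------------------

_SINGLE_KETS = {
    "0": np.array([1.0, 0.0]),
    "1": np.array([0.0, 1.0]),
    "+": np.array([1.0, 1.0]) / np.sqrt(2.0),
    "-": np.array([1.0, -1.0]) / np.sqrt(2.0),
}

# Named entangled states, given as ket amplitudes in the computational basis.
_NAMED_KETS: dict[str, np.ndarray] = {}


def _named(name: str, terms: dict[int, float], dim: int) -> None:
    v = np.zeros(dim)
    for idx, a in terms.items():
        v[idx] = a
    _NAMED_KETS[name] = v / np.linalg.norm(v)


_named("bell", {0b00: 1, 0b11: 1}, 4)  # B+ = (|00> + |11>)/sqrt(2)
_named("b+", {0b00: 1, 0b11: 1}, 4)
_named("b-", {0b00: 1, 0b11: -1}, 4)
_named("psi+", {0b01: 1, 0b10: 1}, 4)
_named("psi-", {0b01: 1, 0b10: -1}, 4)
_named("ghz", {0b000: 1, 0b111: 1}, 8)
_named("ghz'", {0b001: 1, 0b110: 1}, 8)  # entangled superposition of 001 and 110
_named("w", {0b001: 1, 0b010: 1, 0b100: 1}, 8)


def ket(token: str) -> np.ndarray:
    """State vector for a basis-string or named-state token."""
    token = token.strip()
    low = token.lower()
    if low in _NAMED_KETS:
        return _NAMED_KETS[low].copy()
    if token and all(c in _SINGLE_KETS for c in token):
        v = _SINGLE_KETS[token[0]]
        for c in token[1:]:
            v = np.kron(v, _SINGLE_KETS[c])
        return v
    raise StateError(f"malformed state token {token!r}")


def parse_state(spec, units: Sequence[str]) -> LabeledState:
    """Build a :class:`LabeledState` from a flexible specification.

    Accepted forms:

    * a basis string over ``{0, 1, +, -}`` (Hadamard-basis tokens map to
      (|0> ± |1>)/sqrt(2)), read left to right in register order;
    * a named state: ``bell``/``b+``, ``b-``, ``psi+``, ``psi-``, ``ghz``,
      ``ghz'``, ``w``;
    * a mixture ``{weight: spec, ...}`` with weights summing to 1;
    * an explicit density matrix (array-like, or the JSON ``[re, im]`` form);
    * a :class:`LabeledState` (checked against ``units`` and passed through).
    """
    units = tuple(units)
    if isinstance(spec, LabeledState):
        if spec.units != units:
            raise StateError(f"state units {spec.units} do not match {units}")
        return spec.validate()
    if isinstance(spec, str):
        v = ket(spec)
        if v.shape[0] != 2 ** len(units):
            raise StateError(
                f"token {spec!r} has dimension {v.shape[0]}, register {units} "
                f"needs {2 ** len(units)}"
            )
        return LabeledState(units, np.outer(v, v.conj()))
    if isinstance(spec, Mapping):
        if "matrix" in spec:
            return LabeledState.from_json({"units": list(units), **spec}).validate()
        # mixture: {spec: weight} (preferred — duplicate weights are fine)
        # or {weight: spec}
        if all(isinstance(k, str) for k in spec):
            pairs = [(float(w), sub) for sub, w in spec.items()]
        else:
            pairs = [(float(w), sub) for w, sub in spec.items()]
        return _mixture(pairs, units)
    if (
        isinstance(spec, Sequence)
        and spec
        and all(isinstance(t, (tuple, list)) and len(t) == 2 for t in spec)
    ):
        return _mixture([(float(w), sub) for w, sub in spec], units)
    m = np.asarray(spec, dtype=complex)
    return LabeledState(units, m).validate()


def _mixture(pairs: list[tuple[float, object]], units: tuple[str, ...]) -> LabeledState:
    weights = [w for w, _ in pairs]
    if abs(sum(weights) - 1.0) > 1e3 * TOL:
        raise StateError(f"mixture weights {weights} do not sum to 1")
    if any(w < -TOL for w in weights):
        raise StateError("mixture weights must be nonnegative")
    m = sum(w * parse_state(sub, units).matrix for w, sub in pairs)
    return LabeledState(units, m).validate()
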