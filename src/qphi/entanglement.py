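"""Entanglement structure: the maximal separability partition P*(rho).

P*(rho) is the finest grouping of a state's qubits such that rho is a convex
mixture of products across the groups, every term of the mixture factorizing
under the *same* partition.  Entangled blocks are treated downstream as
indivisible causal units when repertoires are factorized.

Deciding multipartite mixed-state separability exactly is an open problem in
general; this module implements a cascade that is exact for every regime the
analysis actually visits on 2-3 qubit registers:

1. pure states: a part splits off iff its reduced state is pure;
2. two-qubit mixed states: the Peres-Horodecki positive-partial-transpose
   (PPT) criterion, exact for 2x2 cuts;
3. explicit product factorization or diagonality in a product basis
   (classically correlated mixtures), which certifies separability with an
   explicit shared decomposition;
4. otherwise PPT across every induced bipartition, a *necessary* condition
   only, surfaced with the method tag ``ppt-heuristic``.

A negative partial transpose across any induced cut rejects a candidate
partition definitively in all regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iproduct
from typing import Iterable, Sequence

import numpy as np

from .qstate import (
    DEG_TOL,
    TOL,
    LabeledState,
    StateError,
    compose,
    partial_trace,
)

_PAULI_BASES = {
    "Z": np.eye(2),
    "X": np.array([[1, 1], [1, -1]]) / np.sqrt(2.0),
    "Y": np.array([[1, 1], [1j, -1j]]) / np.sqrt(2.0),
}


@dataclass(frozen=True)
class SeparabilityPartition:
    """The maximal partition P* of a state into mutually unentangled parts."""

    parts: tuple[tuple[str, ...], ...]
    method: str

    @property
    def r(self) -> int:
        return len(self.parts)

    def to_json(self) -> dict:
        return {"parts": [list(p) for p in self.parts], "method": self.method}


def is_pure(rho: LabeledState, tol: float = TOL) -> bool:
    """True iff tr(rho^2) = 1 within tolerance."""
    return abs(rho.purity() - 1.0) < 1e3 * tol


# ---------------------------------------------------------------------------
# Set-partition candidates
# ---------------------------------------------------------------------------


def set_partitions(items: Sequence[str]) -> list[tuple[tuple[str, ...], ...]]:
    """All set partitions of ``items``, each part and partition canonically
    ordered by first appearance in ``items``."""
    items = list(items)
    if not items:
        return [()]
    head, rest = items[0], items[1:]
    out = []
    for sub in set_partitions(rest):
        # head joins an existing part, or opens its own
        for i in range(len(sub)):
            out.append(sub[:i] + ((head,) + sub[i],) + sub[i + 1 :])
        out.append(((head,),) + sub)
    return out


def _candidates(units: Sequence[str]) -> list[tuple[tuple[str, ...], ...]]:
    parts = set_partitions(tuple(units))
    order = {u: i for i, u in enumerate(units)}

    def canon(p):
        return tuple(
            sorted((tuple(sorted(blk, key=order.get)) for blk in p),
                   key=lambda b: order[b[0]])
        )

    cands = sorted({canon(p) for p in parts}, key=lambda p: (-len(p), p))
    return cands


# ---------------------------------------------------------------------------
# PPT
# ---------------------------------------------------------------------------


def partial_transpose(rho: LabeledState, subset: Iterable[str]) -> np.ndarray:
    """Transpose the tensor factors of ``subset`` (matrix returned)."""
    subset = set(subset)
    n = rho.n_units
    axes = list(range(2 * n))
    for i, u in enumerate(rho.units):
        if u in subset:
            axes[i], axes[i + n] = axes[i + n], axes[i]
    t = rho.matrix.reshape([2] * (2 * n)).transpose(axes)
    return t.reshape(rho.dim, rho.dim)


def min_ppt_eigenvalue(rho: LabeledState, subset: Iterable[str]) -> float:
    return float(np.linalg.eigvalsh(partial_transpose(rho, subset)).min().real)


def is_separable_across(
    rho: LabeledState, bipartition: tuple[Iterable[str], Iterable[str]],
    tol: float = TOL,
) -> bool:
    """PPT test across one bipartition.

    Exact for two-qubit states (2x2 cut); for larger registers a negative
    result is definitive (entangled) while a positive result is the PPT
    *heuristic* for separability.
    """
    a, b = set(bipartition[0]), set(bipartition[1])
    if a | b != set(rho.units) or (a & b) or not a or not b:
        raise StateError(f"invalid bipartition ({a}, {b}) of {rho.units}")
    return min_ppt_eigenvalue(rho, a) >= -1e3 * tol


# ---------------------------------------------------------------------------
# Separability certificates
# ---------------------------------------------------------------------------


def _is_product(rho: LabeledState, parts, tol: float) -> bool:
    factors = [partial_trace(rho, p) for p in parts]
    prod = compose(factors).reorder(rho.units)
    return bool(np.abs(prod.matrix - rho.matrix).max() < 1e3 * tol)


def _part_bases(rho: LabeledState, part: tuple[str, ...]) -> list[np.ndarray]:
    """Candidate orthonormal bases for one part's factor space."""
    red = partial_trace(rho, part)
    evals, evecs = np.linalg.eigh(red.matrix)
    bases = [evecs]
    degenerate = np.any(np.abs(np.diff(np.sort(evals))) < DEG_TOL)
    if degenerate and len(part) == 1:
        bases = [_PAULI_BASES["Z"], _PAULI_BASES["X"], _PAULI_BASES["Y"]]
    elif degenerate:
        bases.append(np.eye(red.dim))
    return bases


def _diagonal_in_product_basis(rho: LabeledState, parts, tol: float) -> bool:
    """Search a small family of product bases for one that diagonalizes rho.

    The family combines, per part, the eigenbasis of the part's reduced state
    (unique when non-degenerate) with the three Pauli eigenbases for
    degenerate single-qubit parts.  Diagonality in a product basis certifies
    a shared product decomposition term by term.
    """
    ordered = sorted(parts, key=lambda p: rho.units.index(p[0]))
    per_part = [_part_bases(rho, p) for p in ordered]
    # permute the state so its factors line up with the part order
    unit_seq = tuple(u for p in ordered for u in p)
    perm_state = rho.reorder(unit_seq)
    for combo in iproduct(*per_part):
        B = combo[0]
        for b in combo[1:]:
            B = np.kron(B, b)
        m = B.conj().T @ perm_state.matrix @ B
        if np.abs(m - np.diag(np.diag(m))).max() < 1e3 * tol:
            return True
    return False


# ---------------------------------------------------------------------------
# P* computation
# ---------------------------------------------------------------------------


def _test_candidate(rho: LabeledState, parts, tol: float) -> str | None:
    """Return a method tag if ``parts`` is (certified or presumed) separable."""
    for part in parts:
        if min_ppt_eigenvalue(rho, part) < -1e3 * tol:
            return None  # NPT: definitively entangled across this cut
    if is_pure(rho, tol):
        for part in parts:
            if abs(partial_trace(rho, part).purity() - 1.0) > 1e3 * tol:
                return None
        return "pure-reduction"
    if _is_product(rho, parts, tol):
        return "product-basis"
    if _diagonal_in_product_basis(rho, parts, tol):
        return "product-basis"
    if rho.n_units == 2:
        return "two-qubit-exact"  # PPT is exact for the single 2x2 cut
    return "ppt-heuristic"


def pure_state_partition(
    psi: LabeledState, tol: float = TOL
) -> SeparabilityPartition:
    """Finest partition of a pure state into parts with pure reduced states."""
    if not is_pure(psi, tol):
        raise StateError("pure_state_partition requires a pure state")
    for cand in _candidates(psi.units):
        if len(cand) == 1:
            return SeparabilityPartition(cand, "pure-reduction")
        if all(
            abs(partial_trace(psi, p).purity() - 1.0) < 1e3 * tol for p in cand
        ):
            return SeparabilityPartition(cand, "pure-reduction")
    raise AssertionError("unreachable: coarsest partition is always valid")


def mixed_state_partition(
    rho: LabeledState, tol: float = TOL
) -> SeparabilityPartition:
    """The maximal partition P*(rho) for any (pure or mixed) state.

    Candidates are scanned from finest to coarsest (descending part count,
    lexicographic tie-break); the first candidate passing the separability
    cascade wins.  The coarsest single-part partition is always valid.
    """
    if rho.n_units == 1:
        return SeparabilityPartition((rho.units,), "pure-reduction"
                                     if is_pure(rho, tol) else "coarsest")
    if is_pure(rho, tol):
        return pure_state_partition(rho, tol)
    for cand in _candidates(rho.units):
        if len(cand) == 1:
            return SeparabilityPartition(cand, "coarsest")
        method = _test_candidate(rho, cand, tol)
        if method is not None:
            return SeparabilityPartition(cand, method)
    raise AssertionError("unreachable: coarsest partition is always valid")
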