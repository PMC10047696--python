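"""Quantum cause and effect repertoires with causal marginalization.

The *effect repertoire* of a mechanism state m over a purview Z is the
density matrix the mechanism, and nothing else, pins down for Z after one
application of the channel: the mechanism's complement is replaced by
maximally mixed (uniform interventional) noise, the channel applied, the
result reduced onto Z, and then factorized across the maximal separability
partition P* of that reduced state so that correlations induced by shared
noise from outside the mechanism are discounted while genuine entanglement
within Z is preserved.

The *cause repertoire* runs the adjoint channel backwards from the
mechanism's P*-parts separately (each part composed with maximally mixed
noise), combines the per-part backward conditionals by operator product over
the purview space, and normalizes by the trace.  The asymmetry between the
two directions mirrors the classical formalism: conditional independence
holds for the present given the past, not vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import channels as ch
from .qstate import TOL, LabeledState, StateError, compose, maximally_mixed, partial_trace
from .entanglement import mixed_state_partition


class UndefinedCauseError(ValueError):
    """Raised when the cause-repertoire operator product has zero trace."""


@dataclass(frozen=True)
class Mechanism:
    """A subset of the register in a specific (possibly mixed) state."""

    units: tuple[str, ...]
    state: LabeledState

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        if self.state.units != self.units:
            raise StateError(
                f"mechanism state units {self.state.units} != {self.units}"
            )

    @staticmethod
    def from_system(rho: LabeledState, units: Iterable[str]) -> "Mechanism":
        units = tuple(u for u in rho.units if u in set(units))
        return Mechanism(units, partial_trace(rho, units))


@dataclass(frozen=True)
class Repertoire:
    """A repertoire: density matrix over a purview plus its provenance."""

    purview: tuple[str, ...]
    state: LabeledState
    direction: str  # "cause" | "effect"
    factorization: tuple[tuple[str, ...], ...] = ()
    defined: bool = field(default=True)

    @property
    def matrix(self) -> np.ndarray:
        return self.state.matrix

    def to_json(self) -> dict:
        return {
            "purview": list(self.purview),
            "direction": self.direction,
            "factorization": [list(p) for p in self.factorization],
            "defined": self.defined,
            **self.state.to_json(),
        }


def _register_subset(full: tuple[str, ...], subset: Iterable[str]) -> tuple[str, ...]:
    sub = set(subset)
    return tuple(u for u in full if u in sub)


def raw_conditional(
    T: ch.UnitaryChannel,
    m: Mechanism,
    Z: Iterable[str],
    direction: str = "effect",
) -> LabeledState:
    """The joint conditional state over Z, before P* factorization.

    Effect: tr_{Z'} U (rho^M (x) rho_mm^{M'}) U^dagger.
    Cause:  tr_{Z'} U^dagger (rho^M (x) rho_mm^{M'}) U  (unitary only).
    """
    Z = _register_subset(T.units, Z)
    if not Z:
        raise StateError("raw_conditional: purview must be nonempty")
    if direction not in ("cause", "effect"):
        raise StateError(f"unknown direction {direction!r}")
    if direction == "cause" and not isinstance(T, ch.UnitaryChannel):
        raise ch.UnsupportedDynamicsError(
            "cause repertoires require unitary dynamics"
        )
    rest = tuple(u for u in T.units if u not in set(m.units))
    pieces = [m.state] if not rest else [m.state, maximally_mixed(rest)]
    joint = compose(pieces).reorder(T.units)
    out = ch.apply(T, joint) if direction == "effect" else ch.apply_adjoint(T, joint)
    return partial_trace(out, Z)


def effect_repertoire(
    T: ch.UnitaryChannel, m: Mechanism, Z: Iterable[str], _cache: dict | None = None
) -> Repertoire:
    """Definition-level effect repertoire: P*-factorized joint conditional."""
    Z = _register_subset(T.units, Z)
    key = None
    if _cache is not None:
        key = ("effect", m.units, _state_key(m.state), Z)
        hit = _cache.get(key)
        if hit is not None:
            return hit
    raw = raw_conditional(T, m, Z, "effect")
    pstar = mixed_state_partition(raw)
    if pstar.r == 1:
        rep = Repertoire(Z, raw, "effect", pstar.parts)
    else:
        factors = [raw_conditional(T, m, part, "effect") for part in pstar.parts]
        state = compose(factors).reorder(Z)
        rep = Repertoire(Z, state, "effect", pstar.parts)
    if _cache is not None:
        _cache[key] = rep
    return rep


def cause_repertoire(
    T: ch.UnitaryChannel, m: Mechanism, Z: Iterable[str], _cache: dict | None = None
) -> Repertoire:
    """Definition-level cause repertoire.

    The mechanism state is split into its P* parts; each part's backward
    conditional over Z is computed with everything else maximally mixed; the
    parts are combined by operator product and trace-normalized.  Operands
    commute (are simultaneously diagonalizable) for all states treated here;
    if they do not, the product is symmetrized to (X + X^dagger)/2 and the
    repertoire flagged via a warning.
    """
    Z = _register_subset(T.units, Z)
    key = None
    if _cache is not None:
        key = ("cause", m.units, _state_key(m.state), Z)
        hit = _cache.get(key)
        if hit is not None:
            return hit
    pstar = mixed_state_partition(m.state)
    prod: np.ndarray | None = None
    for part in pstar.parts:
        part_mech = Mechanism(part, partial_trace(m.state, part))
        sigma = raw_conditional(T, part_mech, Z, "cause")
        prod = sigma.matrix if prod is None else prod @ sigma.matrix
    assert prod is not None
    herm_residual = np.abs(prod - prod.conj().T).max()
    if herm_residual > 1e3 * TOL:
        import warnings

        warnings.warn(
            "cause repertoire operands do not commute; symmetrizing "
            f"(anti-Hermitian residual {herm_residual:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    prod = (prod + prod.conj().T) / 2.0
    tr = float(np.trace(prod).real)
    if tr < TOL:
        rep = Repertoire(
            Z, LabeledState(Z, np.zeros_like(prod)), "cause", pstar.parts,
            defined=False,
        )
        if _cache is not None:
            _cache[key] = rep
        return rep
    rep = Repertoire(Z, LabeledState(Z, prod / tr), "cause", pstar.parts)
    if _cache is not None:
        _cache[key] = rep
    return rep


def repertoire(
    T: ch.UnitaryChannel,
    m: Mechanism,
    Z: Iterable[str],
    direction: str,
    _cache: dict | None = None,
) -> Repertoire:
    """Dispatch on direction."""
    if direction == "effect":
        return effect_repertoire(T, m, Z, _cache)
    if direction == "cause":
        return cause_repertoire(T, m, Z, _cache)
    raise StateError(f"unknown direction {direction!r}")


def unconstrained(Z: Iterable[str], direction: str = "effect") -> Repertoire:
    """The unconstrained repertoire: maximally mixed on Z, both directions."""
    Z = tuple(Z)
    return Repertoire(Z, maximally_mixed(Z), direction, tuple((u,) for u in Z))


def _state_key(state: LabeledState) -> bytes:
    return np.round(state.matrix, 12).tobytes()
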