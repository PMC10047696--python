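"""Purview optimization, distinctions and system-wide unfolding.

A *distinction* is a mechanism together with the purview over which its
integrated information is maximal, the intrinsic state on that purview, the
phi value, and the minimum information partition that certified it.
Unfolding a system transition evaluates every nonempty mechanism subset of
the register: effect-side mechanisms take their states from the input state
rho_t, cause-side mechanisms from the output rho_{t+1} = U rho_t U^dagger.
With the identity channel the analysis reads out the constraints a state
places on itself (its intrinsic structure); causes and effects then coincide
and a single "constraint" value is reported per mechanism.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable

import numpy as np

from . import channels as ch
from .qstate import LabeledState, StateError
from .repertoires import Mechanism
from .qid import InformationValue, IntrinsicState
from .partitions import DisintegratingPartition, PartitionedScore, find_mip

_PHI_TOL = 1e-9


@dataclass(frozen=True)
class Distinction:
    """A mechanism's maximally irreducible cause or effect."""

    mechanism: Mechanism
    direction: str  # "cause" | "effect" | "constraint"
    phi: float
    purview: tuple[str, ...]
    intrinsic_state: IntrinsicState | None
    mip: DisintegratingPartition
    intrinsic_information: float
    purview_ties: tuple[tuple[str, ...], ...] = field(default=())
    partition_ties: tuple[DisintegratingPartition, ...] = field(default=())

    @property
    def order(self) -> int:
        """Mechanism order: number of units in the mechanism."""
        return len(self.mechanism.units)

    def to_json(self) -> dict:
        state_json = None
        if self.intrinsic_state is not None:
            labels = self.intrinsic_state.basis_labels()
            state_json = {
                "eigenvalue": round(self.intrinsic_state.eigenvalue, 6),
                "degenerate": self.intrinsic_state.is_degenerate,
                "basis_labels": labels,
                "vectors": [
                    [[float(z.real), float(z.imag)] for z in
                     self.intrinsic_state.vectors[:, k]]
                    for k in range(self.intrinsic_state.vectors.shape[1])
                ],
            }
        return {
            "mechanism": list(self.mechanism.units),
            "direction": self.direction,
            "phi": round(self.phi, 6),
            "ii": round(self.intrinsic_information, 6),
            "purview": list(self.purview),
            "intrinsic_state": state_json,
            "mip": self.mip.to_json(),
            "purview_ties": [list(t) for t in self.purview_ties],
        }


@dataclass(frozen=True)
class CauseEffectStructure:
    """All distinctions of one direction, positive-phi and reducible alike."""

    system_state: LabeledState
    channel: ch.UnitaryChannel
    direction: str
    distinctions: tuple[Distinction, ...]
    reducible: tuple[Distinction, ...]

    def __iter__(self):
        return iter(self.distinctions)

    def order_histogram(self) -> tuple[int, ...]:
        """Count of positive-phi mechanisms per order (1-based orders)."""
        n = len(self.channel.units)
        counts = [0] * n
        for d in self.distinctions:
            counts[d.order - 1] += 1
        return tuple(counts)

    def by_mechanism(self) -> dict[tuple[str, ...], Distinction]:
        out = {d.mechanism.units: d for d in self.distinctions}
        out.update({d.mechanism.units: d for d in self.reducible
                    if d.mechanism.units not in out})
        return out

    def to_json(self) -> dict:
        return {
            "direction": self.direction,
            "distinctions": [d.to_json() for d in self.distinctions],
            "reducible": [d.to_json() for d in self.reducible],
            "order_histogram": list(self.order_histogram()),
        }


def _nonempty_subsets(units: tuple[str, ...]) -> list[tuple[str, ...]]:
    return list(
        chain.from_iterable(
            combinations(units, k) for k in range(1, len(units) + 1)
        )
    )


def phi_mechanism(
    T: ch.UnitaryChannel,
    m: Mechanism,
    direction: str = "effect",
    _cache: dict | None = None,
) -> Distinction:
    """Maximize phi(m, Z) over all nonempty purviews Z of the register.

    Ties across purviews of different sizes resolve toward the larger
    purview; remaining same-size ties resolve to the first purview in
    canonical (size, register) order and are reported.
    """
    cache = {} if _cache is None else _cache
    results: list[tuple[tuple[str, ...], PartitionedScore]] = []
    for Z in _nonempty_subsets(T.units):
        results.append((Z, find_mip(T, m, Z, direction, cache)))
    best_phi = max(s.phi for _, s in results)
    if math.isinf(best_phi):
        tied = [(Z, s) for Z, s in results if math.isinf(s.phi)]
    else:
        tied = [(Z, s) for Z, s in results if abs(s.phi - best_phi) <= _PHI_TOL]
    # larger purviews win ties; first canonical among equal sizes
    max_size = max(len(Z) for Z, _ in tied)
    winners = [(Z, s) for Z, s in tied if len(Z) == max_size]
    Zstar, score = winners[0]
    ties = tuple(Z for Z, _ in winners[1:])
    state = score.intrinsic.optimizing_state if score.intrinsic else None
    return Distinction(
        mechanism=m,
        direction=direction,
        phi=max(best_phi, 0.0) if not math.isinf(best_phi) else best_phi,
        purview=Zstar,
        intrinsic_state=state,
        mip=score.partition,
        intrinsic_information=score.intrinsic.value if score.intrinsic else 0.0,
        purview_ties=ties,
        partition_ties=score.ties,
    )


def _structure(
    T: ch.UnitaryChannel,
    rho: LabeledState,
    direction: str,
    label: str,
) -> CauseEffectStructure:
    cache: dict = {}
    positive, reducible = [], []
    for units in _nonempty_subsets(T.units):
        m = Mechanism.from_system(rho, units)
        d = phi_mechanism(T, m, direction, cache)
        if label != direction:
            d = dataclasses.replace(d, direction=label)
        (positive if d.phi > _PHI_TOL else reducible).append(d)
    return CauseEffectStructure(rho, T, label, tuple(positive), tuple(reducible))


@dataclass(frozen=True)
class Unfolding:
    """The result of unfolding a system: one structure per direction."""

    mode: str
    structures: dict

    def __getitem__(self, direction: str) -> CauseEffectStructure:
        return self.structures[direction]

    def to_json(self) -> dict:
        return {
            "mode": self.mode,
            **{k: v.to_json() for k, v in self.structures.items()},
        }


def unfold(
    T: ch.UnitaryChannel | None,
    rho_t: LabeledState,
    mode: str = "transition",
) -> Unfolding:
    """Unfold all mechanisms of a system.

    ``transition``: intrinsic effects of rho_t through T, plus intrinsic
    causes of rho_{t+1} = T rho_t T^dagger.  ``self``: constraint analysis
    under the identity channel (T may be omitted); a single value per
    mechanism, tagged "constraint".
    """
    if mode == "self":
        if T is None:
            T = ch.named_gate("@".join(["I"] * rho_t.n_units), rho_t.units)
        elif np.abs(T.matrix - np.eye(T.dim)).max() > 1e-9:
            raise StateError("self-mode analysis requires the identity channel")
        return Unfolding(
            "self", {"constraint": _structure(T, rho_t, "effect", "constraint")}
        )
    if mode != "transition":
        raise StateError(f"unknown mode {mode!r}")
    if T is None:
        raise StateError("transition mode requires a channel")
    rho_next = ch.apply(T, rho_t.reorder(T.units))
    return Unfolding(
        "transition",
        {
            "effect": _structure(T, rho_t, "effect", "effect"),
            "cause": _structure(T, rho_next, "cause", "cause"),
        },
    )


def compare_structures(
    cs1: CauseEffectStructure, cs2: CauseEffectStructure
) -> dict:
    """Structured diff of two cause-effect structures of equal register size.

    Reports positive-phi counts per mechanism order and per-mechanism phi
    deltas (mechanisms keyed by their unit sets).
    """
    if len(cs1.channel.units) != len(cs2.channel.units):
        raise StateError("structures live on registers of different size")
    h1, h2 = cs1.order_histogram(), cs2.order_histogram()
    d1 = {d.mechanism.units: d.phi for d in cs1.distinctions}
    d2 = {d.mechanism.units: d.phi for d in cs2.distinctions}
    deltas = {}
    for key in sorted(set(d1) | set(d2)):
        a, b = d1.get(key, 0.0), d2.get(key, 0.0)
        if abs(a - b) > _PHI_TOL:
            deltas["".join(key)] = round(b - a, 6)
    return {
        "order_histograms": [list(h1), list(h2)],
        "phi_deltas": deltas,
        "identical": h1 == h2 and not deltas,
    }
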