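"""Disintegrating partitions, partitioned repertoires, phi and the MIP.

A disintegrating partition theta of a mechanism M and purview Z splits the
pair into k >= 2 parts (M(i), Z(i)): the mechanism parts partition M (empty
parts allowed), the purview parts partition Z, no part is (empty, empty),
and if one part carries the whole mechanism it must carry no purview — so
every theta either cuts the mechanism or severs all mechanism-purview
connections.  These partitions are in bijection with the set partitions of
the disjoint union of M and Z into at least two blocks (subject to the
whole-mechanism constraint), which is how they are enumerated.

phi(m, Z, theta) scores the intrinsic state selected from the *unpartitioned*
repertoire against the partitioned repertoire; the minimum information
partition (MIP) minimizes phi normalized by the number of severed
mechanism-unit x purview-unit pairs, and the reported phi is the
*unnormalized* value at the MIP.  Ties in the normalized score are broken
toward the smaller unnormalized phi, then by canonical enumeration order;
ties are recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np

from .qstate import StateError, compose, maximally_mixed, partial_trace
from .entanglement import set_partitions
from .repertoires import Mechanism, Repertoire, repertoire, unconstrained
from .qid import InformationValue, intrinsic_information, value_at_state

_PHI_TOL = 1e-9


@dataclass(frozen=True)
class DisintegratingPartition:
    """An unordered collection of (mechanism-part, purview-part) pairs."""

    parts: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    @property
    def k(self) -> int:
        return len(self.parts)

    @property
    def mechanism(self) -> tuple[str, ...]:
        return tuple(u for mp, _ in self.parts for u in mp)

    @property
    def purview(self) -> tuple[str, ...]:
        return tuple(u for _, zp in self.parts for u in zp)

    def is_total_cut(self) -> bool:
        return all((not mp) or (not zp) for mp, zp in self.parts)

    def __str__(self) -> str:
        def side(t):
            return "".join(t) if t else "∅"

        return " | ".join(f"({side(mp)},{side(zp)})" for mp, zp in self.parts)

    def to_json(self) -> dict:
        return {"parts": [[list(mp), list(zp)] for mp, zp in self.parts]}


@dataclass(frozen=True)
class PartitionedScore:
    """phi at one partition, with its normalization."""

    partition: DisintegratingPartition
    phi: float
    normalization: int
    intrinsic: InformationValue | None = None
    ties: tuple[DisintegratingPartition, ...] = field(default=())

    @property
    def normalized_phi(self) -> float:
        return self.phi / self.normalization

    def to_json(self) -> dict:
        return {
            "partition": self.partition.to_json(),
            "phi": round(self.phi, 6),
            "normalization": self.normalization,
            "normalized_phi": round(self.normalized_phi, 6)
            if not math.isinf(self.phi)
            else "inf",
            "ties": [t.to_json() for t in self.ties],
        }


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _enumerate_cached(
    M: tuple[str, ...], Z: tuple[str, ...]
) -> tuple[DisintegratingPartition, ...]:
    order = {u: i for i, u in enumerate(dict.fromkeys(M + Z))}
    tagged = [("m", u) for u in M] + [("z", u) for u in Z]
    mset = set(M)
    out = []
    for partition in set_partitions(tagged):
        if len(partition) < 2:
            continue
        pairs = []
        ok = True
        for block in partition:
            mp = tuple(sorted((u for tag, u in block if tag == "m"),
                              key=order.get))
            zp = tuple(sorted((u for tag, u in block if tag == "z"),
                              key=order.get))
            if set(mp) == mset and zp:
                ok = False  # a whole-mechanism part must sever the purview
                break
            pairs.append((mp, zp))
        if not ok:
            continue
        pairs.sort(key=lambda p: ([order[u] for u in p[0]],
                                  [order[u] for u in p[1]]))
        out.append(DisintegratingPartition(tuple(pairs)))
    # canonical, deterministic order; deduplicate (set_partitions is already
    # duplicate-free, the set is defensive)
    uniq = sorted(set(out), key=lambda d: str(d))
    return tuple(uniq)


def enumerate_partitions(
    M: Iterable[str], Z: Iterable[str]
) -> list[DisintegratingPartition]:
    """All disintegrating partitions of (M, Z), duplicate-free, canonical."""
    M, Z = tuple(M), tuple(Z)
    if not M or not Z:
        raise StateError("enumerate_partitions: M and Z must be nonempty")
    return list(_enumerate_cached(M, Z))


def total_cut(M: Iterable[str], Z: Iterable[str]) -> DisintegratingPartition:
    M, Z = tuple(M), tuple(Z)
    # part order matches the canonical enumeration (empty-mechanism first)
    return DisintegratingPartition((((), Z), (M, ())))


def normalization_factor(theta: DisintegratingPartition) -> int:
    """Number of mechanism-unit x purview-unit pairs severed by theta."""
    M, Z = theta.mechanism, theta.purview
    kept = sum(len(mp) * len(zp) for mp, zp in theta.parts)
    return len(M) * len(Z) - kept


# ---------------------------------------------------------------------------
# Partitioned repertoires and phi
# ---------------------------------------------------------------------------


def partitioned_repertoire(
    T,
    m: Mechanism,
    Z: Iterable[str],
    theta: DisintegratingPartition,
    direction: str = "effect",
    _cache: dict | None = None,
) -> Repertoire:
    """Tensor product of per-part repertoires under theta.

    Empty mechanism part -> maximally mixed on its purview part; empty
    purview part -> scalar factor 1 (dropped).  Each part's repertoire is
    itself P*-factorized, so the disintegrating partition acts on top of the
    entanglement structure.
    """
    Z = tuple(u for u in T.units if u in set(Z))
    factors = []
    defined = True
    for mp, zp in theta.parts:
        if not zp:
            continue
        if not mp:
            factors.append(maximally_mixed(zp))
            continue
        sub = Mechanism(mp, partial_trace(m.state, mp))
        rep = repertoire(T, sub, zp, direction, _cache)
        defined = defined and rep.defined
        factors.append(rep.state)
    state = compose(factors).reorder(Z)
    parts = tuple(zp for _, zp in theta.parts if zp)
    return Repertoire(Z, state, direction, parts, defined=defined)


def phi_given_partition(
    T,
    m: Mechanism,
    Z: Iterable[str],
    theta: DisintegratingPartition,
    direction: str = "effect",
    intrinsic: InformationValue | None = None,
    _cache: dict | None = None,
) -> PartitionedScore:
    """phi(m, Z, theta): the intrinsic state scored against the partitioned
    repertoire, clamped at zero (irreducibility is non-negative)."""
    Z = tuple(u for u in T.units if u in set(Z))
    if intrinsic is None:
        intrinsic = intrinsic_information(T, m, Z, direction, _cache)
    norm = normalization_factor(theta)
    if intrinsic.value <= _PHI_TOL:
        return PartitionedScore(theta, 0.0, norm, intrinsic)
    part_rep = partitioned_repertoire(T, m, Z, theta, direction, _cache)
    if not part_rep.defined:
        return PartitionedScore(theta, math.inf, norm, intrinsic)
    raw = value_at_state(intrinsic.optimizing_state, part_rep.state)
    phi = raw if math.isinf(raw) else max(raw, 0.0)
    return PartitionedScore(theta, phi, norm, intrinsic)


def find_mip(
    T,
    m: Mechanism,
    Z: Iterable[str],
    direction: str = "effect",
    _cache: dict | None = None,
) -> PartitionedScore:
    """Exhaustive MIP search over all disintegrating partitions of (M, Z).

    Minimizes the normalized phi; returns the winning partition carrying the
    *unnormalized* phi.  If the intrinsic information is zero the repertoire
    equals the maximally mixed state and the total cut scores exactly zero,
    so the search short-circuits.
    """
    Z = tuple(u for u in T.units if u in set(Z))
    intrinsic = intrinsic_information(T, m, Z, direction, _cache)
    if intrinsic.value <= _PHI_TOL:
        theta = total_cut(m.units, Z)
        return PartitionedScore(theta, 0.0, normalization_factor(theta), intrinsic)
    scores = [
        phi_given_partition(T, m, Z, theta, direction, intrinsic, _cache)
        for theta in enumerate_partitions(m.units, Z)
    ]
    best = min(
        range(len(scores)),
        key=lambda i: (scores[i].normalized_phi, scores[i].phi, i),
    )
    win = scores[best]
    ties = tuple(
        s.partition
        for i, s in enumerate(scores)
        if i != best
        and abs(s.normalized_phi - win.normalized_phi) <= _PHI_TOL
        and abs(s.phi - win.phi) <= _PHI_TOL
    )
    return PartitionedScore(win.partition, win.phi, win.normalization,
                            intrinsic, ties)
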