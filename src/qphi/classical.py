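"""Classical IIT 4.0 mechanism-phi engine, used as an independent oracle.

Implements the probability-vector formalism that the quantum pipeline must
converge to for essentially classical state updates (reversible gates
applied to computational basis states): per-unit effect repertoires with
causal marginalization, Bayes-rule cause repertoires, the intrinsic
difference (ID) measure, partitioned repertoires and the normalized MIP
search.  The partition combinatorics (enumeration, normalization factor,
tie-breaking) are shared with the quantum modules so that convergence tests
exercise the genuinely quantum parts — repertoires and the information
measure are independent implementations.

State indexing convention: full-system states are indexed by reading the
unit values in register order as a binary number, leftmost unit = most
significant bit (matching the quantum Kronecker convention, e.g. state
AB=10 is row/column index 2).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from itertools import chain, combinations, product as iproduct
from typing import Iterable, Mapping, Sequence

import numpy as np

from .partitions import (
    DisintegratingPartition,
    enumerate_partitions,
    normalization_factor,
    total_cut,
)

_PHI_TOL = 1e-9


class TPMError(ValueError):
    """Raised for malformed transition probability matrices."""


@dataclass(frozen=True)
class TPM:
    """A full-state transition probability matrix p(s_{t+1} | s_t).

    ``table[s, s']`` is the probability of output state s' given input state
    s, rows summing to one.  Input and output registers carry their own unit
    labels (the same physical units before and after the update may be named
    differently, e.g. AB -> CD).
    """

    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        t = np.asarray(self.table, dtype=float)
        d_in, d_out = 2 ** len(self.inputs), 2 ** len(self.outputs)
        if t.shape != (d_in, d_out):
            raise TPMError(f"table shape {t.shape} != ({d_in}, {d_out})")
        if np.abs(t.sum(axis=1) - 1.0).max() > 1e-9 or t.min() < -1e-12:
            raise TPMError("rows must be probability distributions")
        object.__setattr__(self, "table", t)

    @staticmethod
    def from_truth_table(
        table: Mapping[str, str],
        inputs: Sequence[str] | None = None,
        outputs: Sequence[str] | None = None,
    ) -> "TPM":
        n = len(next(iter(table)))
        inputs = tuple(inputs) if inputs else tuple("ABCDEFGH"[:n])
        outputs = tuple(outputs) if outputs else tuple("CDEFGHIJ"[:n])
        t = np.zeros((2**n, 2**n))
        for k, v in table.items():
            t[int(k, 2), int(v, 2)] = 1.0
        return TPM(inputs, outputs, t)

    # -- I/O ---------------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "outputs": list(self.outputs),
            "state_order": "big-endian (leftmost unit = most significant bit)",
            "table": self.table.tolist(),
        }

    @staticmethod
    def from_json(obj: Mapping) -> "TPM":
        return TPM(tuple(obj["inputs"]), tuple(obj["outputs"]),
                   np.array(obj["table"]))

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["# inputs", *self.inputs])
            w.writerow(["# outputs", *self.outputs])
            w.writerow(["# state order", "big-endian"])
            for row in self.table:
                w.writerow([f"{float(x):.17g}" for x in row])

    @staticmethod
    def read_csv(path) -> "TPM":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        inputs = tuple(rows[0][1:])
        outputs = tuple(rows[1][1:])
        table = np.array([[float(x) for x in r] for r in rows[3:]])
        return TPM(inputs, outputs, table)


@dataclass(frozen=True)
class ClassicalRepertoire:
    """A probability vector over the states of a purview."""

    purview: tuple[str, ...]
    probs: np.ndarray
    defined: bool = field(default=True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "purview", tuple(self.purview))
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))


def _unit_index(units: tuple[str, ...], u: str) -> int:
    return units.index(u)


def _states(n: int) -> list[tuple[int, ...]]:
    return list(iproduct((0, 1), repeat=n))


def _idx(bits: Sequence[int]) -> int:
    out = 0
    for b in bits:
        out = (out << 1) | b
    return out


# ---------------------------------------------------------------------------
# Repertoires
# ---------------------------------------------------------------------------


def _single_unit_effect(
    tpm: TPM, m: Mapping[str, int], out_unit: str
) -> np.ndarray:
    """pi_e(Z_i | m): uniform interventional average over non-mechanism
    inputs of the marginal output distribution of one unit."""
    n_in = len(tpm.inputs)
    j = _unit_index(tpm.outputs, out_unit)
    p = np.zeros(2)
    weight = 0.0
    for s in _states(n_in):
        if any(s[_unit_index(tpm.inputs, u)] != v for u, v in m.items()):
            continue
        row = tpm.table[_idx(s)]
        for sp_idx, pr in enumerate(row):
            if pr == 0.0:
                continue
            bit = (sp_idx >> (len(tpm.outputs) - 1 - j)) & 1
            p[bit] += pr
        weight += 1.0
    return p / weight


def classical_effect_repertoire(
    tpm: TPM, m: Mapping[str, int], Z: Iterable[str]
) -> ClassicalRepertoire:
    """Product of per-unit effect repertoires (causal marginalization)."""
    Z = tuple(u for u in tpm.outputs if u in set(Z))
    vec = np.ones(1)
    for u in Z:
        vec = np.kron(vec, _single_unit_effect(tpm, m, u))
    return ClassicalRepertoire(Z, vec)


def unconstrained_effect_repertoire(
    tpm: TPM, Z: Iterable[str], M: Iterable[str]
) -> ClassicalRepertoire:
    """Marginal over all mechanism states of the product effect repertoire."""
    Z = tuple(u for u in tpm.outputs if u in set(Z))
    M = tuple(u for u in tpm.inputs if u in set(M))
    acc = np.zeros(2 ** len(Z))
    for bits in _states(len(M)):
        m = dict(zip(M, bits))
        acc += classical_effect_repertoire(tpm, m, Z).probs
    return ClassicalRepertoire(Z, acc / 2 ** len(M))


def classical_cause_repertoire(
    tpm: TPM, m: Mapping[str, int], Z: Iterable[str]
) -> ClassicalRepertoire:
    """Bayes inversion of the per-mechanism-unit product likelihoods with a
    uniform prior over purview states."""
    Z = tuple(u for u in tpm.inputs if u in set(Z))
    if not m:
        return ClassicalRepertoire(Z, np.full(2 ** len(Z), 1.0 / 2 ** len(Z)))
    like = np.ones(2 ** len(Z))
    for i, z_bits in enumerate(_states(len(Z))):
        z = dict(zip(Z, z_bits))
        for u, v in m.items():
            like[i] *= _single_unit_effect(tpm, z, u)[v]
    total = like.sum()
    if total <= _PHI_TOL:
        return ClassicalRepertoire(Z, np.zeros_like(like), defined=False)
    return ClassicalRepertoire(Z, like / total)


def classical_repertoire(
    tpm: TPM, m: Mapping[str, int], Z: Iterable[str], direction: str
) -> ClassicalRepertoire:
    if direction == "effect":
        return classical_effect_repertoire(tpm, m, Z)
    if direction == "cause":
        return classical_cause_repertoire(tpm, m, Z)
    raise ValueError(f"unknown direction {direction!r}")


def _partitioned(
    tpm: TPM, m: Mapping[str, int], Z: tuple[str, ...],
    theta: DisintegratingPartition, direction: str,
) -> ClassicalRepertoire:
    """Partitioned repertoire: product over theta's parts; an empty
    mechanism part contributes the fully-noised repertoire of its purview."""
    parts: list[tuple[tuple[str, ...], np.ndarray]] = []
    defined = True
    for mp, zp in theta.parts:
        if not zp:
            continue
        sub = {u: m[u] for u in mp}
        rep = classical_repertoire(tpm, sub, zp, direction)
        defined = defined and rep.defined
        parts.append((rep.purview, rep.probs))
    parts.sort(key=lambda pv: min(Z.index(u) for u in pv[0]))
    vec = np.ones(1)
    order: list[str] = []
    for purview, probs in parts:
        vec = np.kron(vec, probs)
        order.extend(purview)
    vec = _permute_probs(vec, tuple(order), Z)
    return ClassicalRepertoire(Z, vec, defined=defined)


def _permute_probs(
    p: np.ndarray, order: tuple[str, ...], target: tuple[str, ...]
) -> np.ndarray:
    if order == target:
        return p
    n = len(order)
    perm = [order.index(u) for u in target]
    return p.reshape([2] * n).transpose(perm).reshape(-1)


# ---------------------------------------------------------------------------
# Intrinsic difference and phi
# ---------------------------------------------------------------------------


def classical_id(
    P: np.ndarray, Q: np.ndarray, tol: float = _PHI_TOL
) -> tuple[float, tuple[int, ...]]:
    """ID(P, Q) = max_alpha p_alpha log2(p_alpha / q_alpha), with the argmax
    state indices (ties grouped)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("distributions must have equal length")
    vals = np.zeros_like(P)
    for a, (p, q) in enumerate(zip(P, Q)):
        if p <= tol:
            vals[a] = 0.0
        elif q <= tol:
            vals[a] = math.inf
        else:
            vals[a] = p * math.log2(p / q)
    best = float(vals.max())
    if math.isinf(best):
        arg = tuple(int(i) for i in np.flatnonzero(np.isinf(vals)))
    else:
        arg = tuple(int(i) for i in np.flatnonzero(np.abs(vals - best) <= 1e-8))
    return max(best, 0.0) if not math.isinf(best) else best, arg


def classical_kld(P: np.ndarray, Q: np.ndarray, tol: float = _PHI_TOL) -> float:
    """Kullback-Leibler divergence in bits (the extrinsic counterpart)."""
    out = 0.0
    for p, q in zip(P, Q):
        if p <= tol:
            continue
        if q <= tol:
            return math.inf
        out += p * math.log2(p / q)
    return out


def _unconstrained(tpm: TPM, Z: tuple[str, ...], M: tuple[str, ...],
                   direction: str) -> ClassicalRepertoire:
    if direction == "effect":
        return unconstrained_effect_repertoire(tpm, Z, M)
    d = 2 ** len(Z)
    return ClassicalRepertoire(Z, np.full(d, 1.0 / d))


@dataclass(frozen=True)
class ClassicalDistinction:
    """Result record of the classical phi pipeline for one mechanism."""

    mechanism: tuple[str, ...]
    mechanism_state: tuple[int, ...]
    direction: str
    phi: float
    purview: tuple[str, ...]
    states: tuple[tuple[int, ...], ...]  # tied intrinsic states, bit tuples
    mip: DisintegratingPartition
    intrinsic_information: float
    purview_ties: tuple[tuple[str, ...], ...] = ()

    def state_labels(self) -> list[str]:
        return ["".join(str(b) for b in s) for s in self.states]


def classical_phi_purview(
    tpm: TPM,
    m: Mapping[str, int],
    Z: Iterable[str],
    direction: str = "effect",
    measure: str = "id",
) -> tuple[float, tuple[int, ...], DisintegratingPartition, float]:
    """phi(m, Z) for a fixed purview: (phi, argmax states, MIP, ii)."""
    side = tpm.outputs if direction == "effect" else tpm.inputs
    mside = tpm.inputs if direction == "effect" else tpm.outputs
    Z = tuple(u for u in side if u in set(Z))
    M = tuple(u for u in mside if u in m)
    rep = classical_repertoire(tpm, m, Z, direction)
    unc = _unconstrained(tpm, Z, M, direction)
    if not rep.defined:
        return 0.0, (), total_cut(M, Z), 0.0
    ii, arg = classical_id(rep.probs, unc.probs)
    if measure == "kld":
        ii = classical_kld(rep.probs, unc.probs)
    if ii <= _PHI_TOL:
        theta = total_cut(M, Z)
        return 0.0, arg, theta, ii
    scores = []
    for theta in enumerate_partitions(M, Z):
        part = _partitioned(tpm, m, Z, theta, direction)
        if not part.defined:
            scores.append((math.inf, theta))
            continue
        if measure == "kld":
            val = classical_kld(rep.probs, part.probs)
        else:
            vals = []
            for a in arg:
                p, q = rep.probs[a], part.probs[a]
                vals.append(math.inf if q <= _PHI_TOL and p > _PHI_TOL
                            else p * math.log2(p / q) if p > _PHI_TOL else 0.0)
            val = max(vals)
        scores.append((max(val, 0.0) if not math.isinf(val) else val, theta))
    norm = [normalization_factor(t) for _, t in scores]
    best = min(range(len(scores)),
               key=lambda i: (scores[i][0] / norm[i], scores[i][0], i))
    return scores[best][0], arg, scores[best][1], ii


def classical_phi(
    tpm: TPM,
    m: Mapping[str, int],
    direction: str = "effect",
    measure: str = "id",
) -> ClassicalDistinction:
    """Maximize phi(m, Z) over purviews, larger purviews winning ties."""
    side = tpm.outputs if direction == "effect" else tpm.inputs
    M = tuple(u for u in (tpm.inputs if direction == "effect" else tpm.outputs)
              if u in m)
    subsets = list(chain.from_iterable(
        combinations(side, k) for k in range(1, len(side) + 1)))
    results = [(Z, classical_phi_purview(tpm, m, Z, direction, measure))
               for Z in subsets]
    best_phi = max(r[1][0] for r in results)
    tied = [r for r in results if
            (math.isinf(r[1][0]) and math.isinf(best_phi)) or
            abs(r[1][0] - best_phi) <= _PHI_TOL]
    size = max(len(r[0]) for r in tied)
    winners = [r for r in tied if len(r[0]) == size]
    (Zstar, (phi, arg, mip, ii)) = winners[0]
    nz = len(Zstar)
    states = tuple(tuple((a >> (nz - 1 - i)) & 1 for i in range(nz))
                   for a in arg)
    return ClassicalDistinction(
        mechanism=M,
        mechanism_state=tuple(m[u] for u in M),
        direction=direction,
        phi=phi,
        purview=Zstar,
        states=states,
        mip=mip,
        intrinsic_information=ii,
        purview_ties=tuple(r[0] for r in winners[1:]),
    )
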