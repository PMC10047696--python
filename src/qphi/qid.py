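"""Quantum intrinsic difference (QID), relative entropy, intrinsic information.

With orthonormal decompositions rho = sum_i p_i |i><i| and
sigma = sum_j q_j |j><j|, and overlap matrix P_ij = |<i|j>|^2, the quantum
relative entropy is

    S(rho||sigma) = sum_i p_i [ log2 p_i - sum_j P_ij log2 q_j ]

and the quantum intrinsic difference replaces the average over i with a
maximum — the information is evaluated at the single eigenstate that is
specified most strongly:

    QID(rho||sigma) = max_i p_i [ log2 p_i - sum_j P_ij log2 q_j ].

The maximizing eigenvector (or, for a degenerate optimum, the spanned
eigenspace) is the *intrinsic state*.  Values carry the unit "ibit": a
pointwise log-ratio weighted by its probability.  QID <= S always, with
equality when rho is pure, and both reduce to their classical counterparts
when rho and sigma commute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .qstate import DEG_TOL, TOL, LabeledState, StateError, eigendecompose
from .repertoires import Mechanism, Repertoire, repertoire, unconstrained


@dataclass(frozen=True)
class IntrinsicState:
    """The optimizing eigenstate(s) of a QID evaluation.

    ``vectors`` holds one eigenvector per column; more than one column means
    the optimum is degenerate and the intrinsic state is the spanned
    eigenspace.
    """

    eigenvalue: float
    vectors: np.ndarray
    units: tuple[str, ...] = ()

    @property
    def is_degenerate(self) -> bool:
        return self.vectors.shape[1] > 1

    def basis_labels(self, tol: float = TOL) -> list[str] | None:
        """Bit-string labels if every vector is a computational basis state."""
        labels = []
        n = int(math.log2(self.vectors.shape[0]))
        for k in range(self.vectors.shape[1]):
            v = self.vectors[:, k]
            idx = np.flatnonzero(np.abs(v) > tol)
            if len(idx) != 1:
                return None
            labels.append(format(int(idx[0]), f"0{n}b"))
        return labels


@dataclass(frozen=True)
class InformationValue:
    """A non-negative information value in ibit, with its optimizer."""

    value: float
    optimizing_state: IntrinsicState
    unit: str = field(default="ibit")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.value)


def _log_terms(q: np.ndarray, P: np.ndarray, tol: float) -> np.ndarray:
    """sum_j P_ij log2 q_j for each i, -inf where support is violated."""
    out = np.zeros(P.shape[0])
    pos = q > tol
    with np.errstate(divide="ignore"):
        logq = np.where(pos, np.log2(np.where(pos, q, 1.0)), 0.0)
    out += P[:, pos] @ logq[pos]
    # weight on sigma's null space -> -inf contribution
    null_weight = P[:, ~pos].sum(axis=1)
    out = np.where(null_weight > tol, -np.inf, out)
    return out


def _pointwise_values(
    rho: LabeledState, sigma: LabeledState, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-eigenvector values p_i [log2 p_i - sum_j P_ij log2 q_j]."""
    if rho.units != sigma.units:
        raise StateError(f"unit mismatch: {rho.units} vs {sigma.units}")
    er = eigendecompose(rho)
    es = eigendecompose(sigma)
    P = np.abs(er.eigenvectors.conj().T @ es.eigenvectors) ** 2
    p = er.eigenvalues
    with np.errstate(divide="ignore"):
        logp = np.where(p > tol, np.log2(np.where(p > tol, p, 1.0)), 0.0)
    cross = _log_terms(es.eigenvalues, P, tol)
    vals = np.where(p > tol, p * (logp - cross), 0.0)
    # p * (-inf) for p > 0 must survive as +inf (support mismatch)
    vals = np.where((p > tol) & np.isneginf(cross), np.inf, vals)
    return vals, p, er.eigenvectors


def qid(rho: LabeledState, sigma: LabeledState, tol: float = TOL) -> InformationValue:
    """Quantum intrinsic difference QID(rho||sigma) in ibit."""
    vals, p, vecs = _pointwise_values(rho, sigma, tol)
    best = float(np.max(vals))
    group = np.flatnonzero(
        np.isinf(vals) if math.isinf(best) else np.abs(vals - best) <= DEG_TOL
    )
    # restrict the degenerate group to eigenvectors sharing the eigenvalue
    group = group[np.abs(p[group] - p[group[0]]) <= DEG_TOL]
    state = IntrinsicState(float(p[group[0]]), vecs[:, group], rho.units)
    return InformationValue(max(best, 0.0) if not math.isinf(best) else best, state)


def quantum_relative_entropy(
    rho: LabeledState, sigma: LabeledState, tol: float = TOL
) -> float:
    """S(rho||sigma) = tr rho log2 rho - tr rho log2 sigma (bits)."""
    vals, _, _ = _pointwise_values(rho, sigma, tol)
    return float(np.sum(vals))


def value_at_state(
    state: IntrinsicState, sigma: LabeledState, tol: float = TOL
) -> float:
    """Evaluate p_i [log2 p_i - sum_j P_ij log2 q_j] at a fixed intrinsic
    state against an arbitrary comparison matrix ``sigma``.

    For a degenerate intrinsic eigenspace the maximum over its basis vectors
    is returned.  Used for integrated information, where the intrinsic state
    is selected against the unconstrained repertoire but scored against a
    partitioned one.
    """
    p = state.eigenvalue
    if p <= tol:
        return 0.0
    es = eigendecompose(sigma)
    P = np.abs(state.vectors.conj().T @ es.eigenvectors) ** 2
    cross = _log_terms(es.eigenvalues, P, tol)
    vals = np.where(np.isneginf(cross), np.inf, p * (math.log2(p) - cross))
    return float(np.max(vals))


def intrinsic_information(
    T,
    m: Mechanism,
    Z,
    direction: str = "effect",
    _cache: dict | None = None,
) -> InformationValue:
    """ii(m, Z): QID of the repertoire against the unconstrained repertoire.

    The optimizing state is the intrinsic cause/effect state — against the
    maximally mixed comparison it is always an eigenvector of maximal
    eigenvalue of the repertoire.
    """
    rep = repertoire(T, m, Z, direction, _cache)
    if not rep.defined:
        return InformationValue(
            0.0, IntrinsicState(0.0, np.zeros((rep.state.dim, 0)), rep.purview)
        )
    return qid(rep.state, unconstrained(rep.purview, direction).state)
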