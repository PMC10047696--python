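"""Disintegrating partitions, partitioned repertoires, phi, and the MIP."""

from itertools import product as iproduct

import numpy as np
import pytest

import qphi as q
from qphi.partitions import total_cut

from conftest import AB, state, mech


def brute_force_partitions(M, Z):
    """Independent oracle: enumerate by labeling every element of M and Z
    with a part index, filter the disintegrating-partition constraints,
    deduplicate unordered part collections."""
    elements = [("m", u) for u in M] + [("z", u) for u in Z]
    n = len(elements)
    seen = set()
    for labels in iproduct(range(n), repeat=n):
        parts = {}
        for (tag, u), lab in zip(elements, labels):
            parts.setdefault(lab, ([], []))[0 if tag == "m" else 1].append(u)
        pairs = []
        ok = True
        for mp, zp in parts.values():
            if not mp and not zp:
                continue
            if set(mp) == set(M) and zp:
                ok = False
                break
            pairs.append((tuple(sorted(mp)), tuple(sorted(zp))))
        if not ok or len(pairs) < 2:
            continue
        seen.add(frozenset(pairs))
    return seen


class TestEnumeration:
    def test_single_pair_has_exactly_the_total_cut(self):
        parts = q.enumerate_partitions(("A",), ("C",))
        assert len(parts) == 1
        assert parts[0].is_total_cut()
        assert set(parts[0].parts) == {(("A",), ()), ((), ("C",))}

    @pytest.mark.parametrize(
        "M,Z",
        [(("A",), ("C",)), (("A",), ("C", "D")), (("A", "B"), ("C",)),
         (("A", "B"), ("C", "D")), (("A", "B", "C"), ("A", "B", "C"))],
    )
    def test_matches_brute_force_oracle(self, M, Z):
        ours = {
            frozenset((tuple(sorted(mp)), tuple(sorted(zp))) for mp, zp in th.parts)
            for th in q.enumerate_partitions(M, Z)
        }
        assert ours == brute_force_partitions(M, Z)

    def test_two_by_two_contains_the_documented_cuts(self):
        thetas = {frozenset(th.parts)
                  for th in q.enumerate_partitions(AB, ("C", "D"))}
        assert frozenset({(("A",), ("C",)), (("B",), ("D",))}) in thetas
        assert frozenset({(("A",), ("D",)), (("B",), ("C",))}) in thetas
        assert frozenset({(("A",), ()), (("B",), ("C", "D"))}) in thetas
        assert frozenset({(("A", "B"), ()), ((), ("C", "D"))}) in thetas

    def test_every_partition_passes_the_invariants(self):
        M, Z = ("A", "B"), ("C", "D")
        for th in q.enumerate_partitions(M, Z):
            mus = [u for mp, _ in th.parts for u in mp]
            zus = [u for _, zp in th.parts for u in zp]
            assert sorted(mus) == sorted(M) and sorted(zus) == sorted(Z)
            assert all(mp or zp for mp, zp in th.parts)
            assert th.k >= 2
            for mp, zp in th.parts:
                if set(mp) == set(M):
                    assert zp == ()


class TestNormalization:
    def test_total_cut_severs_all_pairs(self):
        assert q.normalization_factor(total_cut(AB, ("C", "D"))) == 4

    def test_diagonal_cut_severs_two(self):
        th = q.DisintegratingPartition(
            ((("A",), ("C",)), (("B",), ("D",)))
        )
        assert q.normalization_factor(th) == 2

    def test_minimal_total_cut_is_one(self):
        assert q.normalization_factor(total_cut(("A",), ("C",))) == 1

    def test_always_positive(self):
        for th in q.enumerate_partitions(AB, ("C", "D")):
            assert q.normalization_factor(th) >= 1


class TestPartitionedRepertoire:
    def test_total_cut_gives_maximally_mixed(self, cnot):
        m = mech(state("10"), AB)
        rep = q.partitioned_repertoire(cnot, m, AB, total_cut(AB, AB), "effect")
        assert np.allclose(rep.matrix, np.eye(4) / 4)

    def test_partition_destroys_bell_entanglement(self, cnot):
        m = mech(state("+0"), AB)
        th = q.DisintegratingPartition(((("A",), ("A",)), (("B",), ("B",))))
        rep = q.partitioned_repertoire(cnot, m, AB, th, "effect")
        assert np.allclose(rep.matrix, np.eye(4) / 4)

    def test_cut_away_mechanism_part_noises_its_constraint(self, cnot):
        # severing B from everything leaves A=1 to fix the copy output while
        # the XOR output sees only noise: |1><1| (x) I/2
        m = mech(state("10"), AB)
        th = q.DisintegratingPartition(((("A",), ("A", "B")), (("B",), ())))
        rep = q.partitioned_repertoire(cnot, m, AB, th, "effect")
        assert np.allclose(np.diag(rep.matrix), [0, 0, 0.5, 0.5])
        assert np.allclose(rep.matrix, np.diag(np.diag(rep.matrix)))


class TestPhiGivenPartition:
    def test_first_order_total_cut_one_ibit(self, cnot):
        m = mech(state("10"), ("A",))
        s = q.phi_given_partition(cnot, m, ("A",), total_cut(("A",), ("A",)))
        assert abs(s.phi - 1.0) < 1e-9
        assert s.normalization == 1

    def test_bell_diagonal_cut_two_ibits(self, cnot):
        m = mech(state("+0"), AB)
        th = q.DisintegratingPartition(((("A",), ("A",)), (("B",), ("B",))))
        s = q.phi_given_partition(cnot, m, AB, th)
        assert abs(s.phi - 2.0) < 1e-9
        assert s.normalization == 2

    def test_no_op_partition_scores_zero(self, cnot):
        # 0+ factorizes along (A->A, B->B): partition changes nothing
        m = mech(state("0+"), AB)
        th = q.DisintegratingPartition(((("A",), ("A",)), (("B",), ("B",))))
        s = q.phi_given_partition(cnot, m, AB, th)
        assert abs(s.phi) < 1e-9


class TestFindMip:
    def test_bell_mip_is_total_cut(self, cnot):
        m = mech(state("+0"), AB)
        s = q.find_mip(cnot, m, AB, "effect")
        assert s.partition.is_total_cut()
        assert abs(s.phi - 2.0) < 1e-9
        assert abs(s.normalized_phi - 0.5) < 1e-9

    def test_classical_second_order_reports_unnormalized_one(self, cnot):
        m = mech(state("10"), AB)
        s = q.find_mip(cnot, m, AB, "effect")
        assert abs(s.phi - 1.0) < 1e-9

    def test_reducible_second_order_purview_zero(self, cnot):
        m = mech(state("0+"), AB)
        s = q.find_mip(cnot, m, AB, "effect")
        assert abs(s.phi) < 1e-9

    def test_phi_bounded_by_intrinsic_information(self, cnot):
        for spec in ["10", "0+", "-+", "+0", {"00": 0.5, "11": 0.5}]:
            for units in [("A",), ("B",), AB]:
                m = mech(state(spec), units)
                for Z in [("A",), ("B",), AB]:
                    s = q.find_mip(cnot, m, Z, "effect")
                    assert s.phi <= s.intrinsic.value + 1e-9

    def test_factorizing_channel_is_fully_reducible(self):
        # independent single-qubit gates: the matching cut yields phi = 0
        g = q.named_gate("X⊗H", AB)
        m = mech(state("10"), AB)
        s = q.find_mip(g, m, AB, "effect")
        assert abs(s.phi) < 1e-9
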