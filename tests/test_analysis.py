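"""Purview optimization, unfolding, structure comparison, convergence."""

import itertools

import numpy as np
import pytest

import qphi as q

from conftest import AB, ABC, state, mech


def phi_map(ces):
    return {d.mechanism.units: round(d.phi, 9) for d in ces.distinctions}


class TestPhiMechanism:
    def test_copy_control_first_order(self, cnot):
        d = q.phi_mechanism(cnot, mech(state("10"), ("A",)), "effect")
        assert abs(d.phi - 1.0) < 1e-9
        assert d.purview == ("A",)
        assert d.intrinsic_state.basis_labels() == ["1"]

    def test_xor_output_cause_with_tied_states(self, cnot):
        out = q.apply(cnot, state("10"))
        d = q.phi_mechanism(cnot, mech(out, ("B",)), "cause")
        assert abs(d.phi - 0.5) < 1e-9
        assert d.purview == AB
        assert d.intrinsic_state.is_degenerate
        assert sorted(d.intrinsic_state.basis_labels()) == ["01", "10"]

    def test_mixed_input_whole_mechanism(self, cnot):
        rho = state({"00": 0.5, "11": 0.5})
        d = q.phi_mechanism(cnot, mech(rho, AB), "effect")
        assert abs(d.phi - 1.0) < 1e-9
        assert d.purview == ("B",)
        assert d.intrinsic_state.basis_labels() == ["0"]

    def test_larger_purview_wins_tie(self, cnot):
        d = q.phi_mechanism(cnot, mech(state("10"), AB), "effect")
        assert d.purview == AB  # ties with the single XOR output, larger wins


class TestUnfold:
    def test_cnot_classical_transition_structure(self, cnot):
        u = q.unfold(cnot, state("10"))
        assert phi_map(u["effect"]) == {("A",): 1.0, ("A", "B"): 1.0}
        assert phi_map(u["cause"]) == {("A",): 1.0, ("B",): 0.5, ("A", "B"): 1.0}

    def test_zero_phi_mechanisms_are_retained(self, cnot):
        u = q.unfold(cnot, state("10"))
        reducible = {d.mechanism.units for d in u["effect"].reducible}
        assert ("B",) in reducible

    def test_ghz_constraints_only_third_order(self):
        u = q.unfold(None, state("ghz", ABC), mode="self")
        ces = u["constraint"]
        assert ces.order_histogram() == (0, 0, 1)
        assert ces.distinctions[0].direction == "constraint"

    def test_w_constraints_at_all_orders(self):
        u = q.unfold(None, state("w", ABC), mode="self")
        assert u["constraint"].order_histogram() == (3, 3, 1)

    def test_classical_basis_state_first_order_only(self):
        u = q.unfold(None, state("000", ABC), mode="self")
        assert u["constraint"].order_histogram() == (3, 0, 0)

    def test_self_mode_rejects_non_identity(self, cnot):
        with pytest.raises(q.StateError):
            q.unfold(cnot, state("00"), mode="self")


class TestCompareStructures:
    def test_ghz_vs_w_order_histograms(self):
        ghz = q.unfold(None, state("ghz", ABC), mode="self")["constraint"]
        w = q.unfold(None, state("w", ABC), mode="self")["constraint"]
        diff = q.compare_structures(ghz, w)
        assert diff["order_histograms"] == [[0, 0, 1], [3, 3, 1]]
        assert not diff["identical"]

    def test_structure_equals_itself(self):
        ghz = q.unfold(None, state("ghz", ABC), mode="self")["constraint"]
        diff = q.compare_structures(ghz, ghz)
        assert diff["identical"] and diff["phi_deltas"] == {}

    def test_bell_transition_vs_noninteracting_transition(self, cnot):
        bell = q.unfold(cnot, state("+0"))["effect"]
        flat = q.unfold(cnot, state("0+"))["effect"]
        assert bell.order_histogram() == (0, 1)
        assert flat.order_histogram() == (2, 0)


class TestSubsystemEmbedding:
    def test_disconnected_identity_wire_preserves_distinctions(self, cnot):
        """Embedding the mixed two-qubit analysis in a three-qubit system by
        an identity-extended gate on an entangled pure state preserves the
        subsystem's cause and effect."""
        mixed = state({"00": 0.5, "11": 0.5})
        small = q.unfold(cnot, mixed)
        big = q.unfold(
            q.named_gate("I⊗CNOT", ABC), state("ghz", ABC)
        )
        # effect of the whole two-qubit mechanism: phi=1 onto the XOR wire
        small_eff = phi_map(small["effect"])[("A", "B")]
        big_eff = phi_map(big["effect"])[("B", "C")]
        assert abs(small_eff - big_eff) < 1e-9
        # cause of the XOR output qubit in state 0: phi=0.5
        small_cause = phi_map(small["cause"])[("B",)]
        big_cause = phi_map(big["cause"])[("C",)]
        assert abs(small_cause - big_cause) < 1e-9
        # and the larger system adds distinctions spanning all three qubits
        assert ("A", "B", "C") in phi_map(big["effect"])


class TestClassicalQuantumConvergence:
    """The central convergence requirement: permutation unitaries applied to
    computational basis states reproduce the classical oracle exactly —
    phi values, purviews and intrinsic states, for every mechanism."""

    OUT = {"A": "C", "B": "D"}

    @pytest.mark.parametrize("perm", list(itertools.permutations(range(4))))
    def test_all_two_bit_reversible_gates_all_basis_states(self, perm):
        table = {format(i, "02b"): format(p, "02b") for i, p in enumerate(perm)}
        T = q.from_truth_table(table, AB)
        tpm = q.TPM.from_truth_table(table, AB, ("C", "D"))
        for s in ["00", "01", "10", "11"]:
            rho = q.parse_state(s, AB)
            out_state = q.apply(T, rho)
            out_bits = format(perm[int(s, 2)], "02b")
            for direction in ("effect", "cause"):
                src = rho if direction == "effect" else out_state
                cache = {}
                for units in [("A",), ("B",), AB]:
                    dq = q.phi_mechanism(
                        T, q.Mechanism.from_system(src, units), direction, cache
                    )
                    if direction == "effect":
                        mc = {u: int(s["AB".index(u)]) for u in units}
                    else:
                        mc = {self.OUT[u]: int(out_bits["AB".index(u)])
                              for u in units}
                    dc = q.classical_phi(tpm, mc, direction)
                    assert abs(dq.phi - dc.phi) < 1e-9
                    expected = (tuple(self.OUT[u] for u in dq.purview)
                                if direction == "effect" else dq.purview)
                    assert expected == dc.purview
                    if dq.phi > 1e-9:
                        assert sorted(dq.intrinsic_state.basis_labels()) == \
                            sorted(dc.state_labels())
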