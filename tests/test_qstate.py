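"""Density-matrix core: composition, partial trace, spectra, parsing."""

import numpy as np
import pytest

import qphi as q
from qphi.scenarios import random_density_matrix

from conftest import AB, ABC, state


class TestCompose:
    def test_kron_order_matches_register_order(self):
        s = q.compose([state("1", ("A",)), q.maximally_mixed(("B",))])
        assert s.units == AB
        assert np.allclose(np.diag(s.matrix), [0, 0, 0.5, 0.5])

    def test_single_state_identity(self):
        rho = state("+0")
        assert q.compose([rho]) is not rho
        assert np.allclose(q.compose([rho]).matrix, rho.matrix)

    def test_maximally_mixed_factorizes(self):
        s = q.compose([q.maximally_mixed(("A",)), q.maximally_mixed(("B",))])
        assert np.allclose(s.matrix, np.eye(4) / 4)

    def test_label_collision_rejected(self):
        with pytest.raises(q.StateError, match="collision"):
            q.compose([state("0", ("A",)), state("1", ("A",))])


class TestPartialTrace:
    def test_bell_reduces_to_maximally_mixed(self):
        bell = state("b+", ("C", "D"))
        red = q.partial_trace(bell, {"C"})
        assert red.units == ("C",)
        assert np.allclose(red.matrix, np.eye(2) / 2)

    def test_w_state_two_qubit_reduction(self):
        # tr_C W = (1/3)|00><00| + (2/3)|Psi+><Psi+|
        w = state("w", ABC)
        red = q.partial_trace(w, {"A", "B"})
        psi_plus = np.zeros(4)
        psi_plus[[1, 2]] = 1 / np.sqrt(2)
        expected = np.diag([1 / 3, 0, 0, 0]) + (2 / 3) * np.outer(psi_plus, psi_plus)
        assert np.allclose(red.matrix, expected)

    def test_keep_all_units_is_identity(self):
        rho = state("-+")
        assert np.allclose(q.partial_trace(rho, set(AB)).matrix, rho.matrix)

    def test_not_a_subset_rejected(self):
        with pytest.raises(q.StateError):
            q.partial_trace(state("00"), {"Z"})

    @pytest.mark.parametrize("seed", range(5))
    def test_product_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        a = q.LabeledState(("A",), random_density_matrix(rng, 2))
        b = q.LabeledState(("B",), random_density_matrix(rng, 2))
        joint = q.compose([a, b])
        assert np.allclose(q.partial_trace(joint, {"A"}).matrix, a.matrix)
        assert np.allclose(q.partial_trace(joint, {"B"}).matrix, b.matrix)

    def test_register_order_preserved_for_noncontiguous_keep(self):
        rng = np.random.default_rng(7)
        parts = [q.LabeledState((u,), random_density_matrix(rng, 2)) for u in ABC]
        joint = q.compose(parts)
        red = q.partial_trace(joint, {"A", "C"})
        assert red.units == ("A", "C")
        expected = np.kron(parts[0].matrix, parts[2].matrix)
        assert np.allclose(red.matrix, expected)


class TestEigendecompose:
    def test_pure_state_spectrum(self):
        es = q.eigendecompose(state("1", ("A",)))
        assert np.allclose(es.eigenvalues, [1, 0])
        assert np.allclose(np.abs(es.eigenvectors[:, 0]), [0, 1])

    def test_degenerate_group_flagged(self):
        mix = state({"01": 0.5, "10": 0.5})
        es = q.eigendecompose(mix)
        assert np.allclose(es.eigenvalues, [0.5, 0.5, 0, 0])
        assert es.groups[0] == (0, 1)
        span = es.eigenvectors[:, :2]
        # the degenerate eigenspace spans {|01>, |10>}
        proj = span @ span.conj().T
        assert np.allclose(np.diag(proj).real, [0, 1, 1, 0])

    def test_maximally_mixed_single_group(self):
        es = q.eigendecompose(q.maximally_mixed(AB))
        assert len(es.groups) == 1 and len(es.groups[0]) == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        rho = q.LabeledState(AB, random_density_matrix(rng, 4))
        es = q.eigendecompose(rho)
        assert np.linalg.norm(es.reconstruct() - rho.matrix) < 1e-9

    def test_non_hermitian_rejected(self):
        bad = q.LabeledState(("A",), np.array([[0.5, 0.5], [0.0, 0.5]]))
        with pytest.raises(q.StateError):
            q.eigendecompose(bad)


class TestParseState:
    def test_computational_token(self):
        rho = state("10")
        assert np.allclose(np.diag(rho.matrix), [0, 0, 1, 0])

    def test_hadamard_token(self):
        rho = state("+0")
        v = np.kron([1, 1] / np.sqrt(2), [1, 0])
        assert np.allclose(rho.matrix, np.outer(v, v))

    def test_named_states_normalized(self):
        for name, units in [("b+", AB), ("ghz", ABC), ("w", ABC), ("ghz'", ABC)]:
            rho = state(name, units)
            rho.validate()
            assert abs(rho.purity() - 1.0) < 1e-12

    def test_even_mixture(self):
        rho = state({"00": 0.5, "11": 0.5})
        assert np.allclose(np.diag(rho.matrix), [0.5, 0, 0, 0.5])

    def test_pair_list_mixture(self):
        rho = state([(0.5, "b+"), (0.5, "psi+")], ("C", "D"))
        rho.validate()
        assert abs(rho.purity() - 0.5) < 1e-12

    def test_bad_weights_rejected(self):
        with pytest.raises(q.StateError, match="sum to 1"):
            state({"00": 0.7, "11": 0.7})

    def test_malformed_token_rejected(self):
        with pytest.raises(q.StateError):
            state("2X")

    def test_non_psd_matrix_rejected(self):
        with pytest.raises(q.StateError):
            state(np.diag([1.5, -0.5]), ("A",))

    def test_json_round_trip(self):
        rho = state("b-", AB)
        again = q.LabeledState.from_json(rho.to_json())
        assert again.units == rho.units
        assert np.allclose(again.matrix, rho.matrix)


class TestInvariants:
    @pytest.mark.parametrize(
        "spec,units",
        [("0", ("A",)), ("+", ("A",)), ("10", AB), ("b+", AB),
         ("ghz", ABC), ("w", ABC), ({"00": 0.5, "11": 0.5}, AB)],
    )
    def test_constructors_yield_valid_states(self, spec, units):
        state(spec, units).validate()

    def test_reorder_is_consistent_with_kron(self):
        rng = np.random.default_rng(3)
        a = q.LabeledState(("A",), random_density_matrix(rng, 2))
        b = q.LabeledState(("B",), random_density_matrix(rng, 2))
        ab = q.compose([a, b])
        ba = q.compose([b, a]).reorder(AB)
        assert np.allclose(ab.matrix, ba.matrix)
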