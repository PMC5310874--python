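import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapc.data_model import AdjacencyGraph, MortalityDataset, StudyDimensions
from gapc.errors import GapcError, StructureError
from gapc.inference import constrain
from gapc.simulate import lattice_graph
from gapc.structure import (
    EffectSet,
    ModelSpec,
    cohort_index,
    cohort_index_grid,
    constraint_set,
    delta_constraint_matrix,
    icar_precision,
    interaction_precision,
    linear_predictor,
    rw_precision,
)

DIMS = StudyDimensions(G=2, A=50, I=13, T=24, M=5)


class TestCohortIndex:
    @pytest.mark.parametrize(
        "i,t,expected",
        [(13, 1, 1), (1, 24, 84), (7, 10, 40), (13, 24, 24), (1, 1, 61)],
    )
    def test_index_formula(self, i, t, expected):
        assert cohort_index(i, t, DIMS) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(GapcError):
            cohort_index(0, 1, DIMS)
        with pytest.raises(GapcError):
            cohort_index(1, 25, DIMS)

    def test_maximum_equals_cohort_count(self):
        assert cohort_index(1, DIMS.T, DIMS) == DIMS.K

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        i1=st.integers(1, 13), t1=st.integers(1, 24),
        i2=st.integers(1, 13), t2=st.integers(1, 24),
    )
    def test_equal_cohorts_lie_on_M_diagonals(self, i1, t1, i2, t2):
        """Cells sharing a cohort differ by exactly delta_t = M * delta_i."""
        k1, k2 = cohort_index(i1, t1, DIMS), cohort_index(i2, t2, DIMS)
        if k1 == k2:
            assert (t1 - t2) == DIMS.M * (i1 - i2)

    def test_grid_is_zero_based_shift_of_scalar_map(self):
        grid = cohort_index_grid(DIMS)
        assert grid[12, 0] == 0 and grid[0, 23] == 83


class TestRandomWalkPrecision:
    def test_rw1_n3_closed_form(self):
        sm = rw_precision(3, 1)
        np.testing.assert_allclose(sm.matrix, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])
        assert sm.rank == 2 and sm.numerical_rank() == 2

    def test_rw1_n2_single_difference(self):
        np.testing.assert_allclose(rw_precision(2, 1).matrix, [[1, -1], [-1, 1]])

    @pytest.mark.parametrize("n,order", [(5, 1), (5, 2), (10, 1), (10, 2)])
    def test_rank_and_polynomial_kernel(self, n, order):
        sm = rw_precision(n, order)
        assert sm.numerical_rank() == n - order == sm.rank
        for deg in range(order):
            v = np.arange(n, dtype=float) ** deg
            np.testing.assert_allclose(sm.matrix @ v, 0.0, atol=1e-9)

    def test_too_short_vector_rejected(self):
        with pytest.raises(GapcError):
            rw_precision(2, 2)


class TestIcarPrecision:
    def test_path_graph_closed_form(self):
        g = AdjacencyGraph(n_nodes=3, edges=[(0, 1), (1, 2)])
        np.testing.assert_allclose(
            icar_precision(g).matrix, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )

    def test_row_sums_vanish_and_rank_counts_components(self):
        g = lattice_graph(4, 5)
        sm = icar_precision(g)
        np.testing.assert_allclose(sm.matrix.sum(axis=1), 0.0, atol=1e-12)
        assert sm.numerical_rank() == 20 - 1

    def test_isolated_node_gives_zero_row_and_larger_kernel(self):
        g = AdjacencyGraph(n_nodes=3, edges=[(0, 1)])
        sm = icar_precision(g)
        np.testing.assert_allclose(sm.matrix[2], 0.0)
        assert sm.null_space_basis.shape[1] == 2

    def test_two_disjoint_edges_rank(self):
        g = AdjacencyGraph(n_nodes=4, edges=[(0, 1), (2, 3)])
        assert icar_precision(g).numerical_rank() == 4 - 2

    def test_kernel_spanned_by_component_indicators(self):
        g = AdjacencyGraph(n_nodes=4, edges=[(0, 1), (2, 3)])
        sm = icar_precision(g)
        for v in sm.null_space_basis.T:
            np.testing.assert_allclose(sm.matrix @ v, 0.0, atol=1e-10)


class TestInteractionPrecision:
    def setup_method(self):
        self.Qs = icar_precision(lattice_graph(2, 3))  # A=6, rank 5
        self.Qt = rw_precision(4, 1)                   # T=4, rank 3

    def test_type_I_identity(self):
        sm = interaction_precision("I", self.Qs, self.Qt)
        np.testing.assert_allclose(sm.matrix, np.eye(24))
        assert sm.rank == 24

    @pytest.mark.parametrize(
        "typ,expected_rank", [("II", 6 * 3), ("III", 5 * 4), ("IV", 5 * 3)]
    )
    def test_kronecker_rank_products(self, typ, expected_rank):
        sm = interaction_precision(typ, self.Qs, self.Qt)
        assert sm.rank == expected_rank
        assert sm.numerical_rank() == expected_rank

    def test_unknown_type_rejected(self):
        with pytest.raises(GapcError):
            interaction_precision("V", self.Qs, self.Qt)


class TestConstraints:
    def test_type_iv_independent_count(self):
        C = delta_constraint_matrix("IV", 3, 4)
        assert np.linalg.matrix_rank(C) == 3 + 4 - 1

    def test_type_I_single_constraint(self):
        assert delta_constraint_matrix("I", 3, 4).shape == (1, 12)

    def test_per_gender_rows_for_period_effect(self):
        spec = ModelSpec(dims=StudyDimensions(G=2, A=4, I=4, T=24))
        cs = constraint_set(spec)
        assert cs["alpha"].n_constraints == 2
        assert cs["phi"].n_constraints == 1

    def test_constraint_rows_contain_interaction_kernels(self):
        """Type II/III constraint families annihilate what the structure leaves free."""
        Qs = icar_precision(lattice_graph(2, 2))
        Qt = rw_precision(3, 1)
        for typ in ("II", "III", "IV"):
            sm = interaction_precision(typ, Qs, Qt)
            C = delta_constraint_matrix(typ, 4, 3)
            kern = sm.null_space_basis
            # each kernel vector is reachable from the constraint rows
            resid = kern - C.T @ np.linalg.lstsq(C.T, kern, rcond=None)[0]
            np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_projection_idempotent_and_reduces_quadratic_form(self, seed):
        rng = np.random.default_rng(seed)
        Q = rw_precision(8, 2).matrix
        C = np.ones((1, 8))
        x = rng.normal(size=8)
        p = constrain(x, C)
        np.testing.assert_allclose(constrain(p, C), p, atol=1e-12)
        assert p @ Q @ p >= -1e-10
        assert (C @ p).item() == pytest.approx(0.0, abs=1e-12)


class TestLinearPredictor:
    def _dataset(self, dims, rng):
        return MortalityDataset(
            dims=dims,
            deaths=np.zeros(dims.shape, int),
            population=rng.uniform(1e4, 1e5, size=dims.shape),
        )

    def test_flat_effects_give_constant_rate(self, rng):
        dims = StudyDimensions(G=2, A=3, I=4, T=5)
        spec = ModelSpec(dims=dims)
        eff = EffectSet.zeros(dims)
        eff.beta = np.full(2, np.log(1e-5))
        ds = self._dataset(dims, rng)
        log_rate, log_mu = linear_predictor(eff, ds, spec)
        np.testing.assert_allclose(np.exp(log_rate), 1e-5)
        np.testing.assert_allclose(log_mu, np.log(ds.population) + np.log(1e-5))

    def test_spatial_shift_moves_every_cell_of_that_area(self, rng):
        dims = StudyDimensions(G=2, A=3, I=4, T=5)
        spec = ModelSpec(dims=dims)
        ds = self._dataset(dims, rng)
        eff = EffectSet.zeros(dims)
        base = linear_predictor(eff, ds, spec)[0]
        eff.phi[1] += 0.1
        shifted = linear_predictor(eff, ds, spec)[0]
        np.testing.assert_allclose(shifted[:, 1] - base[:, 1], 0.1)
        np.testing.assert_allclose(shifted[:, [0, 2]], base[:, [0, 2]])

    def test_matches_quadruple_loop_oracle(self, rng):
        dims = StudyDimensions(G=2, A=3, I=4, T=5)
        spec = ModelSpec(dims=dims)
        ds = self._dataset(dims, rng)
        eff = EffectSet(
            beta=rng.normal(size=2),
            alpha=rng.normal(size=(2, 5)),
            gamma=rng.normal(size=(2, 4)),
            kappa=rng.normal(size=(2, dims.K)),
            phi=rng.normal(size=3),
            delta=rng.normal(size=(3, 5)),
        )
        log_rate = linear_predictor(eff, ds, spec)[0]
        for g in range(2):
            for a in range(3):
                for i in range(4):
                    for t in range(5):
                        k = dims.M * (dims.I - (i + 1)) + (t + 1) - 1
                        expected = (
                            eff.beta[g] + eff.alpha[g, t] + eff.gamma[g, i]
                            + eff.kappa[g, k] + eff.phi[a] + eff.delta[a, t]
                        )
                        assert log_rate[g, a, i, t] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        dims = StudyDimensions(G=2, A=3, I=4, T=5)
        other = StudyDimensions(G=2, A=4, I=4, T=5)
        ds = self._dataset(dims, rng)
        with pytest.raises(StructureError):
            linear_predictor(EffectSet.zeros(other), ds, ModelSpec(dims=other))


def test_modelspec_yaml_round_trip(tmp_path):
    spec = ModelSpec(
        dims=StudyDimensions(G=2, A=15, I=6, T=10),
        rw_order={"alpha": 1, "gamma": 2, "kappa": 1},
        interaction_type="IV",
    )
    p = tmp_path / "spec.yaml"
    spec.to_yaml(p)
    back = ModelSpec.from_yaml(p)
    assert back.to_dict() == spec.to_dict()
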