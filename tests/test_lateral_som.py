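"""Lateral-kernel construction, settling dynamics, and entropy readout."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from stroopsom import (ActivationState, DataError, InputSet, LateralSOM,
                       ParameterError, build_lateral_kernels, entropy_bits,
                       max_likelihood_response)
from stroopsom.lateral_som import _decayed

from conftest import make_som


class TestLateralKernels:
    @pytest.mark.parametrize("rows,cols,sigma", [(3, 3, 1.0), (20, 20, 0.25),
                                                 (1, 2, 5.0), (4, 7, 2.0)])
    def test_rows_normalized(self, rows, cols, sigma):
        wp, wm = build_lateral_kernels(rows, cols, sigma)
        np.testing.assert_allclose(wp.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(wm.sum(axis=1), 1.0, atol=1e-12)
        assert (wp >= 0).all() and (wm >= 0).all()

    def test_two_unit_map_inhibition_forced(self):
        # With a single other unit, normalization forces all inhibitory
        # weight onto it.
        _, wm = build_lateral_kernels(1, 2, sigma=3.0)
        assert wm[0, 1] == 1.0 and wm[0, 0] == 0.0

    def test_center_row_matches_bruteforce_gaussian(self):
        # Hand-computed oracle: per-pair Gaussian of grid distance, then
        # row normalization, for the center unit of a 3x3 map.
        sigma = 1.0
        wp, _ = build_lateral_kernels(3, 3, sigma)
        coords = [(r, c) for r in range(3) for c in range(3)]
        center = coords.index((1, 1))
        raw = np.array([
            math.exp(-((r - 1) ** 2 + (c - 1) ** 2) / (2 * sigma**2))
            for r, c in coords])
        np.testing.assert_allclose(wp[center], raw / raw.sum(), atol=1e-12)

    def test_inhibition_uniform_off_diagonal(self):
        _, wm = build_lateral_kernels(3, 3, 1.0)
        off = wm[~np.eye(9, dtype=bool)]
        assert np.ptp(off) == 0.0
        assert np.all(np.diag(wm) == 0.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError):
            build_lateral_kernels(3, 3, 0.0)


class TestInitialActivation:
    def test_scale_one_sums_to_one(self):
        som = make_som(units=[[0.0], [0.3], [1.0]], input_vectors=[[0.0], [1.0]])
        a = som.initial_state([0.2], scale=1.0).activation
        assert a.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_zero_is_all_zero(self):
        som = make_som(units=[[0.0], [1.0]], input_vectors=[[0.0], [1.0]])
        a = som.initial_state([0.5], scale=0.0).activation
        assert np.all(a == 0.0)

    def test_two_unit_map_matches_hand_softmax(self):
        # u0 = c, u1 away from c: nearer unit is more active and the values
        # equal the directly evaluated softmax of -d^2 / (Cm * T).
        T = 0.7
        som = make_som(units=[[0.0], [1.0]], input_vectors=[[0.0], [1.0]],
                       temperature=T)
        cm = som.input_set_.median_pairwise_distance  # = 1
        a = som.initial_state([0.0]).activation
        z = np.array([0.0, -1.0 / (cm * T)])
        expected = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(a, expected, atol=1e-12)
        assert a[0] > a[1]

    def test_permutation_equivariance(self):
        # Relabeling (permuting) units permutes the activations identically.
        rng = np.random.default_rng(0)
        units = rng.uniform(0, 1, size=(12, 3))
        inputs = rng.uniform(0, 1, size=(4, 3))
        som = make_som(units, inputs, rows=3, cols=4)
        perm = rng.permutation(12)
        som_p = make_som(units[perm], inputs, rows=3, cols=4)
        c = rng.uniform(0, 1, size=3)
        a = som.initial_state(c).activation
        a_p = som_p.initial_state(c).activation
        np.testing.assert_allclose(a_p, a[perm], atol=1e-12)

    def test_degenerate_input_set_rejected(self):
        # Identical input vectors make the median pairwise distance zero,
        # so the similarity scale of the softmax is undefined.
        som = make_som(units=[[0.0], [1.0]], input_vectors=[[0.5], [0.5], [0.5]])
        with pytest.raises(DataError):
            som.initial_state([0.5])

    def test_input_set_needs_two_vectors(self):
        with pytest.raises(DataError):
            InputSet(np.array([[1.0, 2.0]]))


class TestSettleStep:
    def test_beta_zero_scales_by_alpha(self):
        som = make_som(units=[[0.0], [0.5], [1.0]], input_vectors=[[0.0], [1.0]],
                       alpha=0.8, beta=0.0)
        v = np.array([0.1, 0.4, 0.2])
        state = ActivationState(v.copy())
        som.settle(state)
        np.testing.assert_array_equal(state.activation, 0.8 * v)
        assert state.t == 1

    def test_beta_zero_closed_form_after_k_steps(self):
        som = make_som(units=np.linspace(0, 1, 6)[:, None],
                       input_vectors=[[0.0], [1.0]], rows=2, cols=3,
                       alpha=0.8, beta=0.0)
        state = som.initial_state([0.3])
        a0 = state.activation.copy()
        som.settle(state, steps=7)
        np.testing.assert_allclose(state.activation, 0.8**7 * a0, atol=1e-15)

    def test_zero_activation_is_fixed_point(self):
        som = make_som(units=np.zeros((4, 2)) + np.arange(4)[:, None],
                       input_vectors=[[0.0, 0.0], [3.0, 3.0]], rows=2, cols=2)
        state = ActivationState(np.zeros(4))
        som.settle(state, steps=5)
        assert np.all(state.activation == 0.0)

    @pytest.mark.parametrize("rows,cols", [(3, 3), (5, 5), (2, 4)])
    def test_matches_elementwise_loop_oracle(self, rows, cols):
        # Brute-force double loop over units: a'_i = max(0, alpha a_i +
        # beta * sum_j a_j (w+_ji - w-_ji)) reading each incoming weight.
        rng = np.random.default_rng(rows * 10 + cols)
        n = rows * cols
        units = rng.uniform(0, 1, size=(n, 3))
        som = make_som(units, rng.uniform(0, 1, (3, 3)), rows=rows, cols=cols,
                       alpha=0.8, beta=0.1, sigma=1.0)
        a = rng.uniform(0, 1, size=n)
        wp, wm = som.excitatory_, som.inhibitory_
        expected = np.empty(n)
        for i in range(n):
            lateral = 0.0
            for j in range(n):
                lateral += a[j] * (wp[j, i] - wm[j, i])
            expected[i] = max(0.0, 0.8 * a[i] + 0.1 * lateral)
        state = ActivationState(a.copy())
        som.settle(state)
        np.testing.assert_allclose(state.activation, expected, atol=1e-12)

    def test_positive_homogeneity(self):
        # Scaling the state scales the settled state by the same factor.
        rng = np.random.default_rng(5)
        som = make_som(rng.uniform(0, 1, (9, 2)), rng.uniform(0, 1, (3, 2)),
                       rows=3, cols=3, sigma=1.0)
        a = rng.uniform(0, 1, size=9)
        s1 = ActivationState(a.copy())
        s2 = ActivationState(3.5 * a)
        som.settle(s1, 4)
        som.settle(s2, 4)
        np.testing.assert_allclose(s2.activation, 3.5 * s1.activation,
                                   rtol=1e-12)


class TestLikelihoodReadout:
    def _four_unit_som(self):
        # Units at 0, 0.1, 0.9, 1.0 with inputs 0 and 1: Voronoi cells
        # {0, 1} and {2, 3}.
        return make_som(units=[[0.0], [0.1], [0.9], [1.0]],
                        input_vectors=[[0.0], [1.0]], rows=2, cols=2)

    def test_hand_set_activation_distribution(self):
        som = self._four_unit_som()
        dist = som.likelihood(np.array([0.1, 0.2, 0.3, 0.4]))
        np.testing.assert_allclose(dist, [0.3, 0.7], atol=1e-12)

    def test_point_mass_when_single_cell_active(self):
        som = self._four_unit_som()
        dist = som.likelihood(np.array([0.5, 0.25, 0.0, 0.0]))
        np.testing.assert_allclose(dist, [1.0, 0.0], atol=1e-12)

    def test_voronoi_cells_partition_units(self):
        som = self._four_unit_som()
        assert som.cell_matrix_.sum() == som.n_units_
        assert np.all(som.cell_matrix_.sum(axis=0) == 1.0)

    def test_all_zero_activation_is_undetermined(self):
        som = self._four_unit_som()
        assert som.likelihood(np.zeros(4)) is None
        assert som.readout_entropy(np.zeros(4)) == pytest.approx(1.0)  # log2(2)


class TestEntropyBits:
    @pytest.mark.parametrize("dist,expected", [
        (np.full(16, 1 / 16), 4.0),
        (np.array([1.0, 0.0, 0.0]), 0.0),
        (np.array([0.5, 0.5]), 1.0),
    ])
    def test_closed_forms(self, dist, expected):
        assert entropy_bits(dist) == pytest.approx(expected, abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(DataError):
            entropy_bits(np.array([1.2, -0.2]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.001, max_value=1.0),
                    min_size=2, max_size=16))
    def test_bounded_by_log_cardinality(self, raw):
        dist = np.array(raw) / np.sum(raw)
        h = entropy_bits(dist)
        assert 0.0 <= h <= math.log2(len(dist)) + 1e-9


class TestMaxLikelihoodResponse:
    def test_unique_maximum(self):
        assert max_likelihood_response(
            np.array([0.1, 0.8, 0.1]), ["a", "b", "c"]) == "b"

    def test_exact_tie_takes_first_label(self):
        assert max_likelihood_response(np.array([0.5, 0.5]), ["a", "b"]) == "a"

    def test_undetermined_distribution(self):
        assert max_likelihood_response(None, ["a", "b"]) is None


class TestDecaySchedule:
    def test_schedule_endpoints(self):
        assert _decayed(0.2, 0.05, 0, 1000) == pytest.approx(0.2)
        assert _decayed(0.2, 0.05, 999, 1000) == pytest.approx(0.05)
        assert _decayed(2.0, 0.25, 0, 1000) == pytest.approx(2.0)
        assert _decayed(2.0, 0.25, 999, 1000) == pytest.approx(0.25)

    def test_exponential_interpolation(self):
        # Log-space midpoint: geometric mean of the endpoints.
        mid = _decayed(2.0, 0.5, 500, 1001)
        assert mid == pytest.approx(1.0)


class TestTraining:
    def test_negligible_learning_rate_leaves_units(self, lexicon):
        som = LateralSOM(rows=6, cols=6, epochs=2, eta_start=1e-12,
                         eta_end=1e-12, seed=0)
        som.fit(lexicon.semantic_input_set)
        ref = LateralSOM(rows=6, cols=6, epochs=2, eta_start=1e-12,
                         eta_end=1e-12, seed=0)
        # Reproduce the untouched initialization.
        rng = np.random.default_rng(0)
        X = lexicon.semantic_input_set.vectors
        init = rng.uniform(X.min(0), X.max(0), size=(36, 3))
        np.testing.assert_allclose(som.units_, init, atol=1e-9)
        del ref

    def test_training_is_seed_reproducible(self, lexicon):
        kw = dict(rows=8, cols=8, epochs=20, seed=42)
        a = LateralSOM(**kw).fit(lexicon.semantic_input_set)
        b = LateralSOM(**kw).fit(lexicon.semantic_input_set)
        np.testing.assert_array_equal(a.units_, b.units_)

    def test_trained_map_is_topologically_ordered(self, default_model):
        # Every color owns at least one map unit, and grid neighbors carry
        # more similar feature vectors than random unit pairs.
        som = default_model.semantic_map_
        counts = np.bincount(som.cells_, minlength=16)
        assert (counts > 0).all()
        units = som.units_.reshape(som.rows, som.cols, -1)
        neigh = np.concatenate([
            np.linalg.norm(units[1:] - units[:-1], axis=-1).ravel(),
            np.linalg.norm(units[:, 1:] - units[:, :-1], axis=-1).ravel()])
        rng = np.random.default_rng(0)
        i, j = rng.integers(0, som.n_units_, size=(2, 2000))
        keep = i != j
        rand = np.linalg.norm(som.units_[i[keep]] - som.units_[j[keep]], axis=1)
        assert neigh.mean() < 0.5 * rand.mean()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            LateralSOM(sigma_end=3.0)._check_params()  # above sigma_start
        with pytest.raises(ParameterError):
            LateralSOM(alpha=0.0)._check_params()
        with pytest.raises(ParameterError):
            LateralSOM(beta=-0.1)._check_params()
        with pytest.raises(ParameterError):
            LateralSOM(eta_end=0.5)._check_params()  # above eta_start


class TestSelfNaming:
    def test_trained_maps_name_their_inputs(self, default_model):
        # Presenting a training input and settling to the 1-bit criterion
        # recovers that input's label on both maps.
        for som in (default_model.semantic_map_, default_model.lexical_map_):
            for i, name in enumerate(som.labels_):
                label, steps, conv = som.respond(som.input_set_.vectors[i])
                assert conv and steps < 500
                assert label == name, f"{name} misnamed as {label}"


class TestSerialization:
    def test_json_round_trip(self, tmp_path, lexicon):
        som = LateralSOM(rows=6, cols=6, epochs=5, seed=1).fit(
            lexicon.semantic_input_set)
        path = tmp_path / "som.json"
        som.to_json(path)
        back = LateralSOM.from_json(path)
        np.testing.assert_array_equal(back.units_, som.units_)
        assert back.labels_ == som.labels_
        np.testing.assert_array_equal(back.cells_, som.cells_)
        # Dynamics agree after the round trip.
        c = lexicon.semantic_input_set.vectors[0]
        np.testing.assert_array_equal(back.initial_state(c).activation,
                                      som.initial_state(c).activation)
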