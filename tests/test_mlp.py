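"""Unit tests for the shallow MLP: forward pass, training, influence extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netswarm import (
    MLPModel,
    TrainConfig,
    forward,
    init_mlp,
    linearized_influence,
    train_mlp,
)
from netswarm.errors import DataError, ParameterError, ShapeError, TrainingDivergenceError
from netswarm.mlp import standardize_train_val


def _random_model(rng, n_inputs=4, n_hidden=3, activation="tanh", scale=0.5):
    return MLPModel(
        W_in=rng.uniform(-scale, scale, (n_inputs, n_hidden)),
        b_hidden=rng.uniform(-scale, scale, n_hidden),
        W_out=rng.uniform(-scale, scale, n_hidden),
        b_out=rng.uniform(-scale, scale),
        activation=activation,
    )


class TestInit:
    def test_zero_init_scale_gives_all_zero_weights(self):
        model = init_mlp(3, TrainConfig(init_scale=0.0, seed=1))
        assert np.all(model.W_in == 0) and np.all(model.W_out == 0)
        assert np.all(model.b_hidden == 0) and model.b_out == 0

    def test_same_seed_gives_identical_parameters(self):
        cfg = TrainConfig(seed=11)
        a, b = init_mlp(5, cfg), init_mlp(5, cfg)
        np.testing.assert_array_equal(a.W_in, b.W_in)
        np.testing.assert_array_equal(a.W_out, b.W_out)

    def test_zero_sizes_are_shape_errors(self):
        with pytest.raises(ShapeError):
            init_mlp(0, TrainConfig())
        with pytest.raises(ShapeError):
            TrainConfig(n_hidden=0)

    def test_config_range_validation(self):
        with pytest.raises(ParameterError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ParameterError):
            TrainConfig(momentum=1.0)
        with pytest.raises(ParameterError):
            TrainConfig(patience=50, max_epochs=10)


class TestForward:
    def test_all_zero_model_outputs_bias(self, rng):
        model = MLPModel(np.zeros((4, 2)), np.zeros(2), np.zeros(2), 0.7, "tanh")
        for _ in range(3):
            assert forward(model, rng.standard_normal(4)) == 0.7

    def test_tanh_at_zero_input_with_zero_hidden_bias_outputs_bias(self, rng):
        model = _random_model(rng)
        model.b_hidden = np.zeros(3)
        assert forward(model, np.zeros(4)) == pytest.approx(model.b_out, abs=1e-15)

    @pytest.mark.parametrize("activation", ["tanh", "linear"])
    def test_matches_independent_two_layer_recomputation(self, rng, activation):
        model = _random_model(rng, activation=activation)
        x = rng.standard_normal(4)
        hidden_pre = model.W_in.T @ x + model.b_hidden
        hidden = np.tanh(hidden_pre) if activation == "tanh" else hidden_pre
        expected = float(model.W_out @ hidden + model.b_out)
        assert forward(model, x) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_is_shape_error(self, rng):
        with pytest.raises(ShapeError):
            forward(_random_model(rng), np.zeros(5))


class TestTrain:
    def test_learns_y_equals_two_x(self):
        x = np.linspace(-1, 1, 20)[:, None]
        y = 2.0 * x.ravel()
        cfg = TrainConfig(
            n_hidden=1, activation="linear", l2_penalty=0.0, learning_rate=0.05,
            max_epochs=500, patience=500, early_stopping=False, seed=3,
        )
        res = train_mlp(x, y, x[:4], y[:4], cfg)
        assert res.train_loss_history[-1] < 1e-4

    def test_zero_targets_with_zero_init_stop_at_patience_with_model_unchanged(self):
        X = np.ones((6, 2))
        y = np.zeros(6)
        cfg = TrainConfig(init_scale=0.0, patience=7, max_epochs=100, seed=0)
        res = train_mlp(X, y, X, y, cfg)
        assert res.train_loss_history[0] == 0.0
        assert res.stopped_epoch == 7
        assert np.all(res.model.W_in == 0) and np.all(res.model.W_out == 0)

    def test_huge_l2_penalty_shrinks_all_weights(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        cfg = TrainConfig(
            l2_penalty=1e6, learning_rate=1e-7, momentum=0.0,
            max_epochs=3000, patience=3000, early_stopping=False, seed=1,
        )
        res = train_mlp(X, y, X, y, cfg)
        assert np.max(np.abs(res.model.W_in)) < 1e-2
        assert np.max(np.abs(res.model.W_out)) < 1e-2

    def test_non_finite_inputs_are_data_errors(self):
        X = np.array([[np.nan], [1.0]])
        with pytest.raises(DataError):
            train_mlp(X, [0, 1], X, [0, 1], TrainConfig())

    def test_divergence_raises_and_names_the_epoch(self, rng):
        X = rng.standard_normal((10, 3)) * 10
        y = rng.standard_normal(10) * 10
        cfg = TrainConfig(learning_rate=50.0, momentum=0.9, max_epochs=200,
                          patience=200, seed=0)
        with pytest.raises(TrainingDivergenceError, match="epoch"):
            train_mlp(X, y, X, y, cfg)

    def test_training_loss_non_increasing_without_momentum_or_penalty(self, rng):
        X = rng.standard_normal((25, 4))
        y = X @ rng.standard_normal(4) + 0.1 * rng.standard_normal(25)
        cfg = TrainConfig(
            learning_rate=0.01, momentum=0.0, l2_penalty=0.0,
            max_epochs=300, patience=300, early_stopping=False, seed=2,
        )
        res = train_mlp(X, y, X[:5], y[:5], cfg)
        hist = np.array(res.train_loss_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_returned_model_achieves_the_best_recorded_validation_mse(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        Xv = rng.standard_normal((8, 5))
        yv = rng.standard_normal(8)
        res = train_mlp(X, y, Xv, yv, TrainConfig(max_epochs=100, patience=20, seed=4))
        refit_val = float(np.mean((res.model.predict(Xv) - yv) ** 2))
        assert refit_val == pytest.approx(min(res.val_loss_history), abs=1e-12)


class TestLinearizedInfluence:
    def test_linear_activation_equals_weight_product_exactly(self, rng):
        model = _random_model(rng, activation="linear")
        X = rng.standard_normal((6, 4))
        np.testing.assert_array_equal(
            linearized_influence(model, X), model.W_in @ model.W_out
        )

    def test_zero_output_weights_give_zero_influence(self, rng):
        model = _random_model(rng)
        model.W_out = np.zeros(3)
        assert np.all(linearized_influence(model, rng.standard_normal((5, 4))) == 0)

    def test_tanh_influence_matches_central_finite_differences(self, rng):
        model = _random_model(rng, n_inputs=5, n_hidden=4)
        X = rng.standard_normal((7, 5))
        influence = linearized_influence(model, X)
        h = 1e-5
        fd = np.zeros(5)
        for i in range(5):
            e = np.zeros(5)
            e[i] = h
            fd[i] = np.mean(
                [(forward(model, x + e) - forward(model, x - e)) / (2 * h) for x in X]
            )
        np.testing.assert_allclose(influence, fd, atol=1e-4)

    def test_equivariant_under_input_permutation(self, rng):
        model = _random_model(rng, n_inputs=6)
        X = rng.standard_normal((9, 6))
        perm = rng.permutation(6)
        permuted = MLPModel(
            model.W_in[perm], model.b_hidden, model.W_out, model.b_out, model.activation
        )
        np.testing.assert_array_equal(
            linearized_influence(permuted, X[:, perm]),
            linearized_influence(model, X)[perm],
        )

    def test_empty_reference_is_a_data_error(self, rng):
        with pytest.raises(DataError):
            linearized_influence(_random_model(rng), np.empty((0, 4)))


class TestSerialization:
    def test_json_round_trip(self, rng):
        model = _random_model(rng)
        clone = MLPModel.from_json(model.to_json())
        np.testing.assert_array_equal(clone.W_in, model.W_in)
        np.testing.assert_array_equal(clone.W_out, model.W_out)
        assert clone.b_out == model.b_out and clone.activation == model.activation


class TestStandardize:
    def test_statistics_come_from_the_training_split_only(self, rng):
        Xtr = rng.standard_normal((30, 3)) * 4 + 2
        Xva = rng.standard_normal((10, 3))
        Ztr, Zva, mu, sd = standardize_train_val(Xtr, Xva)
        np.testing.assert_allclose(Ztr.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Ztr.std(axis=0), 1, atol=1e-12)
        np.testing.assert_allclose(Zva, (Xva - mu) / sd, atol=1e-15)

    def test_constant_columns_pass_through_centred(self):
        Xtr = np.ones((5, 2))
        Ztr, Zva, _, sd = standardize_train_val(Xtr, Xtr)
        assert np.all(sd == 1.0)
        assert np.all(Ztr == 0)
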