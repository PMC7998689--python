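"""Network evaluation, the analytic Jacobian, Levenberg-Marquardt behaviour
and model serialization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surftens.data import (
    FluidRecord,
    NormalizationSpec,
    split_dataset,
)
from surftens.exceptions import ModelFileError, TrainingError
from surftens.network import (
    MLPNetwork,
    TrainingConfig,
    lm_jacobian,
    load_model,
    n_parameters,
    save_model,
    sigmoid,
    sigmoid_decreasing,
    train_lm,
)

from conftest import make_teacher, teacher_dataset, toy_dataset


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(0.0) == 0.5

    def test_hand_value(self):
        assert sigmoid(2.0) == pytest.approx(0.880797, abs=5e-7)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-700, 700, allow_nan=False))
    def test_symmetry_identity(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_saturates_without_overflow(self):
        assert sigmoid(1e4) == 1.0
        assert sigmoid(-1e4) == 0.0

    def test_decreasing_variant_is_mirror(self):
        x = np.linspace(-5, 5, 11)
        assert np.allclose(sigmoid_decreasing(x), sigmoid(-x))


def _tiny_net(**overrides):
    """One-hidden-neuron net with hand-friendly weights and norms."""
    kw = dict(
        input_names=("Tr", "Tb", "omega"),
        hidden_weights=[[2.0, 0.0, 0.0]],
        hidden_biases=[-1.0],
        output_weights=[0.5],
        output_bias=0.1,
        input_norms=(NormalizationSpec("Tr", 0.0, 1.0),
                     NormalizationSpec("Tb", 300.0, 700.0),
                     NormalizationSpec("omega", 0.0, 1.0)),
        output_norm=NormalizationSpec("sigma", 0.0, 0.08),
    )
    kw.update(overrides)
    return MLPNetwork(**kw)


class TestForward:
    def test_parameter_count_formula(self):
        assert n_parameters(3, 41) == 206
        net = MLPNetwork(
            input_names=("Tr", "Tb", "omega"),
            hidden_weights=np.zeros((41, 3)), hidden_biases=np.zeros(41),
            output_weights=np.zeros(41), output_bias=0.0,
            input_norms=(NormalizationSpec("Tr", 0, 1),
                         NormalizationSpec("Tb", 0, 1),
                         NormalizationSpec("omega", 0, 1)),
            output_norm=NormalizationSpec("sigma", 0, 1))
        assert net.n_params == 206

    def test_zero_network_returns_output_vmin(self):
        net = _tiny_net(hidden_weights=[[0.0, 0.0, 0.0]], hidden_biases=[0.0],
                        output_weights=[0.0], output_bias=0.0)
        sig = net.predict_features(np.array([[0.3, 450.0, 0.5]]))
        assert sig[0] == pytest.approx(net.output_norm.vmin)

    def test_hand_chain_single_neuron(self):
        # x = (0.75, Tb=500, w=0.2); only Tr enters: z = 2*0.75 - 1 = 0.5
        # h = s(0.5) = 0.62245933; y = 0.5 h + 0.1 = 0.41122967
        # sigma = 0.08 * y = 0.032898373
        net = _tiny_net()
        sig = net.predict_features(np.array([[0.75, 500.0, 0.2]]))
        h = 1.0 / (1.0 + np.exp(-0.5))
        assert sig[0] == pytest.approx(0.08 * (0.5 * h + 0.1), rel=1e-12)

    def test_batch_equals_per_row(self):
        net = make_teacher()
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.uniform(0.25, 0.92, 8),
                             rng.uniform(300, 680, 8),
                             rng.uniform(0.3, 1.1, 8)])
        batch = net.predict_features(X)
        rows = [net.predict_features(X[i:i + 1])[0] for i in range(8)]
        # identical up to BLAS summation order
        assert np.allclose(batch, rows, rtol=1e-12, atol=0)

    def test_predict_computes_reduced_temperature(self):
        net = make_teacher()
        fluid = FluidRecord(name="f", Tc=600.0, Tb=400.0, omega=0.5)
        direct = net.predict_features(np.array([[300.0 / 600.0, 400.0, 0.5]]))
        via_fluid = net.predict(fluid, 300.0)
        assert np.allclose(direct, via_fluid)

    def test_extrapolation_flagged_not_rejected(self):
        net = make_teacher()
        fluid = FluidRecord(name="f", Tc=600.0, Tb=400.0, omega=2.5)  # w > 1.1
        sigma, flags = net.predict(fluid, 300.0, return_flags=True)
        assert flags[0]
        assert np.isfinite(sigma[0])


class TestJacobian:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, seed):
        net = make_teacher(seed=seed)
        rng = np.random.default_rng(seed + 100)
        Xn = rng.uniform(0, 1, (20, 3))
        J = lm_jacobian(net, Xn)
        theta = net.get_params()
        eps = 1e-6
        for p in range(net.n_params):
            tp, tm = theta.copy(), theta.copy()
            tp[p] += eps
            tm[p] -= eps
            net.set_params(tp)
            yp = net.forward_normalized(Xn)
            net.set_params(tm)
            ym = net.forward_normalized(Xn)
            fd = (yp - ym) / (2 * eps)
            np.testing.assert_allclose(J[:, p], fd, rtol=1e-6, atol=1e-9)
            net.set_params(theta)

    def test_decreasing_activation_jacobian_consistent(self):
        net = make_teacher()
        net.activation = "logistic_decreasing"
        Xn = np.random.default_rng(3).uniform(0, 1, (10, 3))
        J = lm_jacobian(net, Xn)
        theta = net.get_params()
        eps = 1e-6
        tp, tm = theta.copy(), theta.copy()
        tp[0] += eps
        tm[0] -= eps
        net.set_params(tp)
        yp = net.forward_normalized(Xn)
        net.set_params(tm)
        fd = (yp - net.forward_normalized(Xn)) / (2 * eps)
        np.testing.assert_allclose(J[:, 0], fd, rtol=1e-6, atol=1e-9)


class TestTraining:
    def _linear_dataset(self):
        # sigma depends linearly on Tr only
        rows = []
        fluid = FluidRecord(name="a", Tc=600.0, Tb=400.0, omega=0.4)
        for Tr in np.linspace(0.3, 0.9, 120):
            rows.append(("a", Tr * 600.0, 0.05 - 0.03 * Tr))
        return toy_dataset(rows, fluids=[fluid])

    def test_one_neuron_learns_linear_target(self):
        # single-input (Tr only) net: the other features are constant here
        ds = self._linear_dataset()
        split = split_dataset(ds, seed=0)
        net, results = train_lm(
            ds, split, 1,
            TrainingConfig(restarts=3, seed=1, max_iterations=500),
            input_names=("Tr",))
        assert min(r.train_rmse for r in results) < 1e-4

    def test_accepted_steps_never_increase_training_rmse(self):
        ds = teacher_dataset(noise_sd=0.01, n_fluids=8)
        split = split_dataset(ds, seed=2)
        _, results = train_lm(
            ds, split, 3, TrainingConfig(restarts=1, seed=5,
                                         max_iterations=60))
        train_curve = [h[1] for h in results[0].history]
        assert all(b <= a + 1e-15 for a, b in zip(train_curve, train_curve[1:]))

    def test_same_seed_is_bit_identical(self):
        ds = teacher_dataset(noise_sd=0.01, n_fluids=6)
        split = split_dataset(ds, seed=2)
        cfg = TrainingConfig(restarts=2, seed=9, max_iterations=40)
        net1, _ = train_lm(ds, split, 3, cfg)
        net2, _ = train_lm(ds, split, 3, cfg)
        assert (net1.get_params() == net2.get_params()).all()

    def test_winner_has_lowest_test_rmse(self):
        ds = teacher_dataset(noise_sd=0.02, n_fluids=6)
        split = split_dataset(ds, seed=2)
        _, results = train_lm(
            ds, split, 3, TrainingConfig(restarts=4, seed=0,
                                         max_iterations=40))
        rmses = [r.test_rmse for r in results]
        assert rmses[0] == min(rmses)

    def test_all_restarts_failing_raises(self):
        ds = self._linear_dataset()
        split = split_dataset(ds, seed=0)
        bad = TrainingConfig(restarts=2, seed=0, initial_damping=1.0,
                             max_damping=1e-6)
        with pytest.raises(TrainingError):
            train_lm(ds, split, 2, bad, input_names=("Tr",))


class TestSerialization:
    def test_round_trip_predictions_exact(self, tmp_path):
        net = make_teacher()
        path = tmp_path / "m.json"
        save_model(net, path)
        loaded = load_model(path)
        X = np.random.default_rng(1).uniform(0, 1, (15, 3))
        X[:, 1] = X[:, 1] * 380 + 300
        assert np.array_equal(net.predict_features(X),
                              loaded.predict_features(X))

    def test_hand_written_file_loads_and_predicts(self, tmp_path):
        doc = {
            "schema_version": 1,
            "architecture": [3, 1, 1],
            "activation": "logistic",
            "input_names": ["Tr", "Tb", "omega"],
            "input_norms": [
                {"name": "Tr", "vmin": 0.0, "vmax": 1.0},
                {"name": "Tb", "vmin": 300.0, "vmax": 700.0},
                {"name": "omega", "vmin": 0.0, "vmax": 1.0}],
            "output_norm": {"name": "sigma", "vmin": 0.0, "vmax": 0.08},
            "hidden_weights": [[2.0, 0.0, 0.0]],
            "hidden_biases": [-1.0],
            "output_weights": [0.5],
            "output_bias": 0.1,
        }
        path = tmp_path / "hand.json"
        path.write_text(json.dumps(doc))
        net = load_model(path)
        h = 1.0 / (1.0 + np.exp(-0.5))
        sig = net.predict_features(np.array([[0.75, 500.0, 0.2]]))
        assert sig[0] == pytest.approx(0.08 * (0.5 * h + 0.1), rel=1e-12)

    def test_tampered_weight_count_names_expected_206(self, tmp_path):
        net = MLPNetwork(
            input_names=("Tr", "Tb", "omega"),
            hidden_weights=np.zeros((41, 3)), hidden_biases=np.zeros(41),
            output_weights=np.zeros(41), output_bias=0.0,
            input_norms=(NormalizationSpec("Tr", 0, 1),
                         NormalizationSpec("Tb", 0, 1),
                         NormalizationSpec("omega", 0, 1)),
            output_norm=NormalizationSpec("sigma", 0, 1))
        path = tmp_path / "m.json"
        save_model(net, path)
        doc = json.loads(path.read_text())
        doc["hidden_biases"] = doc["hidden_biases"][:-1]  # drop one bias
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFileError, match="206"):
            load_model(path)

    def test_schema_version_mismatch(self, tmp_path):
        net = make_teacher()
        path = tmp_path / "m.json"
        save_model(net, path)
        doc = json.loads(path.read_text())
        doc["schema_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFileError, match="schema version"):
            load_model(path)
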