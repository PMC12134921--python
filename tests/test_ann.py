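"""Risk-network tests: forward-pass oracle, export round-trips,
stepwise selection behaviour and regression evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

from exalarm.ann import (ANNConfig, ANNModel, evaluate_regression,
                         monte_carlo_splits, predict_risk, stepwise_select,
                         train_final)
from exalarm.features import FeatureDatabase


def make_model(rng, n_in=3, hidden=4, transform="none"):
    return ANNModel(
        selected_inputs=[f"x{i}" for i in range(n_in)],
        x_mean=rng.normal(size=n_in), x_sd=0.5 + rng.random(n_in),
        y_mean=100.0, y_sd=40.0,
        W1=rng.normal(size=(n_in, hidden)), b1=rng.normal(size=hidden),
        w2=rng.normal(size=hidden), b2=float(rng.normal()),
        hidden=hidden, target_transform=transform,
    )


def make_db(X, tte, patient_ids=None, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "tte", tte)
    if patient_ids is None:
        patient_ids = [f"P{i % 10:02d}" for i in range(len(df))]
    df.insert(0, "anchor_day", np.arange(len(df)))
    df.insert(0, "patient_id", patient_ids)
    return FeatureDatabase(["f"], df, df.iloc[0:0], {"feature_order": names})


class TestForwardPass:
    def test_matches_hand_computed_matrix_algebra(self, rng):
        model = make_model(rng)
        for _ in range(10):
            x = rng.normal(size=3)
            z = (x - model.x_mean) / model.x_sd
            h = 1.0 / (1.0 + np.exp(-(model.W1.T @ z + model.b1)))
            expected = model.y_mean + model.y_sd * (model.w2 @ h + model.b2)
            assert predict_risk(model, x[None, :])[0] == pytest.approx(
                expected, abs=1e-10)

    def test_zero_weights_give_output_bias(self, rng):
        model = make_model(rng)
        model.W1[:] = 0.0
        model.b1[:] = 0.0
        model.w2[:] = 0.0
        model.b2 = 0.25
        expected = model.y_mean + model.y_sd * 0.25
        out = predict_risk(model, rng.normal(size=(5, 3)))
        assert np.allclose(out, expected)

    def test_log_transform_inverts_to_days(self, rng):
        model = make_model(rng, transform="log1p")
        model.y_mean, model.y_sd = math.log1p(200.0), 1e-12
        model.w2[:] = 0.0
        assert predict_risk(model, rng.normal(size=(2, 3)))[0] == pytest.approx(200.0)

    def test_missing_input_named(self, rng):
        model = make_model(rng)
        df = pd.DataFrame({"x0": [1.0], "x1": [2.0]})
        with pytest.raises(ValueError, match="x2"):
            predict_risk(model, df)


class TestExport:
    def test_json_round_trip_preserves_predictions(self, rng):
        model = make_model(rng, transform="log1p")
        clone = ANNModel.from_json(model.to_json())
        X = rng.normal(size=(50, 3))
        assert np.allclose(predict_risk(model, X), predict_risk(clone, X),
                           rtol=0, atol=1e-12)

    def test_rendered_formula_reproduces_predictions(self, rng):
        model = make_model(rng, transform="log1p")
        model.y_mean, model.y_sd = 4.0, 1.0   # log1p-scale output
        X = rng.normal(size=(100, 3))
        preds = predict_risk(model, X)
        for row, expected in zip(X, preds):
            ns = {"exp": math.exp, **{f"x{i}": row[i] for i in range(3)}}
            for line in model.formula().splitlines():
                name, expr = line.split(" = ")
                ns[name] = eval(expr, {"__builtins__": {}}, ns)  # noqa: S307
            assert ns["risk"] == pytest.approx(expected, rel=1e-9)


class TestMonteCarloSplits:
    def test_patient_level_disjoint_and_complete(self):
        pids = np.repeat([f"P{i}" for i in range(10)], 7)
        (tr, val, te), = monte_carlo_splits(pids, (0.6, 0.2, 0.2), 1, seed=0)
        groups = [set(pids[i] for i in idx) for idx in (tr, val, te)]
        assert not (groups[0] & groups[1] or groups[0] & groups[2]
                    or groups[1] & groups[2])
        assert len(tr) + len(val) + len(te) == len(pids)


class TestStepwiseSelect:
    def test_planted_noiseless_signal_found_at_step_one(self):
        rng = np.random.default_rng(0)
        n = 300
        X = rng.normal(size=(n, 6))
        tte = np.clip(100 + 60 * X[:, 2], 0, 200)
        db = make_db(X, tte)
        cfg = ANNConfig(max_steps=2, n_mc_splits=2, epochs=300, seed=1)
        trace = stepwise_select(db, cfg)
        assert trace.steps[0].chosen == "f2"

    def test_trace_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        tte = np.clip(100 + 50 * X[:, 0] + 10 * rng.normal(size=200), 0, 200)
        db = make_db(X, tte)
        cfg = ANNConfig(max_steps=2, n_mc_splits=1, epochs=150, seed=3)
        a = stepwise_select(db, cfg)
        b = stepwise_select(db, cfg)
        assert a.selected_inputs == b.selected_inputs
        assert [s.candidate_errors for s in a.steps] == \
            [s.candidate_errors for s in b.steps]

    def test_chosen_input_minimises_recorded_step_errors(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 5))
        tte = np.clip(100 + 40 * X[:, 1], 0, 200)
        db = make_db(X, tte)
        trace = stepwise_select(db, ANNConfig(max_steps=2, n_mc_splits=2,
                                              epochs=200, seed=4))
        for step in trace.steps:
            assert step.chosen_error == min(step.candidate_errors.values())

    def test_pure_noise_features_give_low_held_out_r2(self):
        r2s = []
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            n = 240
            X = rng.normal(size=(n, 6))
            tte = np.clip(rng.uniform(0, 200, n), 0, 200)
            pids = [f"P{i % 12:02d}" for i in range(n)]
            db = make_db(X, tte, patient_ids=pids)
            cfg = ANNConfig(max_steps=2, n_mc_splits=2, epochs=150, seed=seed)
            trace = stepwise_select(db, cfg)
            model = train_final(db, trace.selected_inputs,
                                ANNConfig(hidden_nodes_grid=(3,), epochs=150,
                                          seed=seed))
            (tr, _, te), = monte_carlo_splits(np.array(pids), (0.6, 0.2, 0.2),
                                              1, seed=seed + 50)
            preds = predict_risk(model, X[te][:, [int(f[1:]) for f in
                                                  model.selected_inputs]])
            r = np.corrcoef(preds, tte[te])[0, 1] if preds.std() > 0 else 0.0
            r2s.append(r * r)
        assert np.mean(r2s) < 0.1

    def test_degenerate_target_rejected(self):
        rng = np.random.default_rng(3)
        db = make_db(rng.normal(size=(50, 3)), np.full(50, 200.0))
        with pytest.raises(ValueError, match="degenerate"):
            stepwise_select(db, ANNConfig())


class TestTrainFinal:
    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 3))
        tte = np.full(120, 200.0)
        db = make_db(X, tte)
        model = train_final(db, ["f0", "f1"],
                            ANNConfig(hidden_nodes_grid=(3,), epochs=100, seed=0))
        preds = predict_risk(model, X[:, :2])
        assert np.allclose(preds, 200.0, atol=1.0)

    def test_planted_linear_signal_recovered(self):
        rng = np.random.default_rng(6)
        n = 600
        X = rng.normal(size=(n, 3))
        tte = np.clip(100 + 45 * X[:, 0] - 30 * X[:, 1], 0, 200)
        db = make_db(X, tte)
        model = train_final(db, ["f0", "f1"],
                            ANNConfig(hidden_nodes_grid=(4, 8), epochs=1200,
                                      patience=200, seed=1))
        (tr, _, te), = monte_carlo_splits(
            db.development["patient_id"].to_numpy(), (0.6, 0.2, 0.2), 1, seed=1)
        preds = predict_risk(model, X[te][:, :2])
        r = np.corrcoef(preds, tte[te])[0, 1]
        assert r * r >= 0.95

    def test_singleton_grid_is_single_fit(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 2))
        tte = np.clip(100 + 30 * X[:, 0], 0, 200)
        db = make_db(X, tte)
        model = train_final(db, ["f0"],
                            ANNConfig(hidden_nodes_grid=(4,), epochs=150, seed=2))
        assert model.hidden == 4

    def test_standardization_uses_training_split_only(self):
        rng = np.random.default_rng(8)
        n = 200
        pids = [f"P{i % 10:02d}" for i in range(n)]
        X = rng.normal(size=(n, 2))
        tte = np.clip(100 + 30 * X[:, 0], 0, 200)
        cfg = ANNConfig(hidden_nodes_grid=(3,), epochs=50, seed=3)
        (tr, val, te), = monte_carlo_splits(np.array(pids), cfg.split_ratios,
                                            1, cfg.seed)
        base = train_final(make_db(X, tte, patient_ids=pids), ["f0", "f1"], cfg)
        X2 = X.copy()
        X2[te] += 5.0   # perturb only unseen test rows
        pert = train_final(make_db(X2, tte, patient_ids=pids), ["f0", "f1"], cfg)
        assert np.array_equal(base.x_mean, pert.x_mean)
        assert np.array_equal(base.x_sd, pert.x_sd)


class TestEvaluateRegression:
    def test_identity_and_sign_flip_give_r2_one(self):
        y = np.array([1.0, 3.0, 7.0, 2.0])
        assert evaluate_regression(y, y)["0"] == pytest.approx(1.0)
        assert evaluate_regression(-y, y)["0"] == pytest.approx(1.0)

    def test_random_pairs_near_zero(self, rng):
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        assert evaluate_regression(a, b)["0"] < 0.02

    def test_zero_variance_predictions_warn(self):
        with pytest.warns(UserWarning):
            out = evaluate_regression(np.ones(5), np.arange(5.0))
        assert out["0"] == 0.0

    def test_per_split_reporting(self):
        y = np.arange(12.0)
        splits = np.repeat(["train", "val", "test"], 4)
        out = evaluate_regression(y, y, splits)
        assert set(out) == {"train", "val", "test"}
        assert all(v == pytest.approx(1.0) for v in out.values())
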