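"""Model zoo: fitting contracts, out-of-fold CV, multistart, stacking."""

import numpy as np
import pandas as pd
import pytest

from odtpredict import (
    ContractError,
    FormulationTable,
    ModelSpec,
    SearchBudget,
    balanced_kfold,
    cross_validate,
    fit,
    load_model,
    multistart_search,
    save_model,
    stack_ensemble,
)
from odtpredict.models import nnls_weights


def _linear_table(n=40, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, n)
    y = 2 * x + 1 + rng.normal(0, noise, n)
    df = pd.DataFrame({"x": x, "Disintegration time [s]": y})
    return FormulationTable(df, {"x": "descriptor", "Disintegration time [s]": "target"})


class TestFit:
    def test_penalized_linear_recovers_exact_line(self):
        table = _linear_table()
        spec = ModelSpec("penalized_linear", {"alpha": 1e-10, "l1_ratio": 0.0}, seed=0)
        model = fit(spec, table.X(), table.y, table.feature_columns)
        pred = model.predict(table.X())
        assert np.allclose(pred, table.y, atol=1e-6)

    def test_determinism_bitwise(self, small_dataset):
        table, _, _ = small_dataset
        spec = ModelSpec("random_forest", {"n_estimators": 50}, seed=3)
        m1 = fit(spec, table.X(), table.y, table.feature_columns)
        m2 = fit(spec, table.X(), table.y, table.feature_columns)
        assert np.array_equal(m1.predict(table.X()), m2.predict(table.X()))

    def test_feedforward_net_trains_and_generalizes(self, small_dataset):
        from odtpredict import r2

        table, truth, _ = small_dataset
        cols = truth.informative_features  # the realistic selected-input case
        X, y = table.X(cols), table.y
        spec = ModelSpec("feedforward_net", {"hidden": (100, 100), "max_iter": 300}, seed=0)
        model = fit(spec, X[:80], y[:80], cols)
        assert model.training_metadata.get("iterations", 1) >= 1
        assert r2(y[80:], model.predict(X[80:])) > 0.0

    def test_missing_values_refused(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ContractError, match="imputation"):
            fit(ModelSpec("random_forest", {}, 0), X, np.array([1.0, 2.0]))

    def test_unknown_family_rejected(self):
        with pytest.raises(ContractError):
            ModelSpec("quantum_forest", {}, 0)

    def test_constant_target_flagged(self):
        X = np.arange(10.0).reshape(-1, 1)
        m = fit(ModelSpec("penalized_linear", {}, 0), X, np.full(10, 7.0))
        assert m.training_metadata.get("constant_target") is True


class TestCrossValidate:
    def test_exact_signal_gives_near_perfect_pooled_metrics(self):
        table = _linear_table(n=50)
        plan = balanced_kfold(table, k=5, seed=0)
        spec = ModelSpec("penalized_linear", {"alpha": 1e-10, "l1_ratio": 0.0}, seed=0)
        cv = cross_validate(spec, table, plan)
        assert cv.pooled.rmse < 1e-5
        assert cv.pooled.r2 > 1 - 1e-9

    def test_mean_predictor_pooled_r2_not_positive(self):
        table = _linear_table(n=50, noise=0.0)
        plan = balanced_kfold(table, k=5, seed=0)
        # huge penalty shrinks the slope to ~0: effectively a mean predictor
        spec = ModelSpec("penalized_linear", {"alpha": 1e9}, seed=0)
        cv = cross_validate(spec, table, plan)
        assert cv.pooled.r2 <= 0.01

    def test_no_leakage_with_memorizing_model(self):
        """A deep forest memorizes random training targets (in-sample R2 near
        1) but cannot predict held-out noise: out-of-fold R2 must stay far
        from 1 if each record is predicted by a model that never saw it."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "a": rng.normal(size=60), "b": rng.normal(size=60),
            "Disintegration time [s]": rng.normal(50, 10, 60),
        })
        table = FormulationTable(df, {"a": "descriptor", "b": "descriptor",
                                      "Disintegration time [s]": "target"})
        spec = ModelSpec("random_forest", {"n_estimators": 100, "min_samples_leaf": 1}, 0)
        model = fit(spec, table.X(), table.y, table.feature_columns)
        from odtpredict import r2
        assert r2(table.y, model.predict(table.X())) > 0.7  # memorized
        plan = balanced_kfold(table, k=5, seed=1)
        cv = cross_validate(spec, table, plan)
        assert cv.pooled.r2 < 0.5
        assert not np.isnan(cv.oof_pred).any()

    def test_each_record_predicted_once(self, small_dataset):
        table, _, _ = small_dataset
        plan = balanced_kfold(table, k=5, seed=2)
        spec = ModelSpec("penalized_linear", {"alpha": 0.1}, 0)
        cv = cross_validate(spec, table, plan)
        assert np.isfinite(cv.oof_pred).all()
        assert len(cv.per_fold) == 5


class TestMultistart:
    def test_single_start_single_family(self, small_dataset):
        table, _, _ = small_dataset
        plan = balanced_kfold(table, k=4, seed=0)
        board = multistart_search(["penalized_linear"], table, plan, n_starts=1, seed=0)
        assert len(board.entries) == 1

    def test_identical_seed_gives_identical_leaderboard(self, small_dataset):
        table, _, _ = small_dataset
        plan = balanced_kfold(table, k=4, seed=0)
        budget = SearchBudget(max_iterations=60)
        kw = dict(n_starts=2, budget=budget, seed=42)
        b1 = multistart_search(["penalized_linear", "gradient_boosting"], table, plan, **kw)
        b2 = multistart_search(["penalized_linear", "gradient_boosting"], table, plan, **kw)
        pd.testing.assert_frame_equal(b1.to_frame(), b2.to_frame())

    def test_dispersion_reported_finite_and_sorted(self, small_dataset):
        table, _, _ = small_dataset
        plan = balanced_kfold(table, k=4, seed=0)
        board = multistart_search(["gradient_boosting"], table, plan, n_starts=4,
                                  budget=SearchBudget(max_iterations=80), seed=1)
        s = board.summary()
        assert np.isfinite(s["sd_rmse"]) and s["sd_rmse"] >= 0
        rmses = [e.mean_rmse for e in board.entries]
        assert rmses == sorted(rmses)

    def test_empty_family_list_rejected(self, small_dataset):
        table, _, _ = small_dataset
        plan = balanced_kfold(table, k=4, seed=0)
        with pytest.raises(ContractError):
            multistart_search([], table, plan)


class TestStacking:
    def test_oracle_base_wins_nearly_all_weight(self):
        rng = np.random.default_rng(0)
        y = rng.normal(50, 20, 200)
        oracle = y.copy()
        noise = rng.normal(50, 20, 200)
        w, c = nnls_weights(np.column_stack([oracle, noise]), y)
        assert w[0] == pytest.approx(1.0, abs=1e-6)
        assert w[1] == pytest.approx(0.0, abs=1e-6)

    def test_identical_bases_share_weight_equally(self):
        rng = np.random.default_rng(1)
        y = rng.normal(50, 20, 100)
        base = y + rng.normal(0, 5, 100)
        other = rng.normal(50, 20, 100)
        w_single, _ = nnls_weights(np.column_stack([base, other]), y)
        w_dup, _ = nnls_weights(np.column_stack([base, base, other]), y)
        assert w_dup[0] == pytest.approx(w_dup[1], rel=1e-9)
        assert w_dup[0] + w_dup[1] == pytest.approx(w_single[0], rel=1e-6)

    def test_ensemble_oof_rmse_not_worse_than_best_base(self):
        from odtpredict import rmse

        rng = np.random.default_rng(2)
        y = rng.normal(50, 20, 150)
        bases = np.column_stack([y + rng.normal(0, s, 150) for s in (5, 10, 20)])
        stacked = stack_ensemble(bases, y)
        ens = stacked.predict(bases)
        assert rmse(y, ens) <= min(rmse(y, bases[:, j]) for j in range(3)) + 1e-9

    def test_stacked_family_fit_end_to_end(self, small_dataset):
        table, _, _ = small_dataset
        spec = ModelSpec("stacked_ensemble", {
            "base_specs": [
                ModelSpec("penalized_linear", {"alpha": 0.01}, 1),
                ModelSpec("gradient_boosting", {"n_estimators": 60}, 2),
            ]}, seed=3)
        model = fit(spec, table.X(), table.y, table.feature_columns)
        pred = model.predict(table.X())
        assert np.isfinite(pred).all()
        assert len(model.training_metadata["meta_weights"]) == 2


class TestBundles:
    def test_save_load_roundtrip_predicts_identically(self, small_dataset, tmp_path):
        table, _, _ = small_dataset
        spec = ModelSpec("gradient_boosting", {"n_estimators": 50}, seed=0)
        model = fit(spec, table.X(), table.y, table.feature_columns)
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        assert back.feature_names == model.feature_names
        assert np.array_equal(back.predict(table.X()), model.predict(table.X()))
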