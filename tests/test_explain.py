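"""Shapley attribution and partial dependence, checked against an
independent brute-force enumeration oracle."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest

from odtpredict import (
    Background,
    ContractError,
    FormulationTable,
    coalition_value,
    exact_shapley,
    kmeans_background,
    partial_dependence,
    sampled_shapley,
    shap_matrix,
)

from conftest import linear_model, toy_model


# ---------------------------------------------------------------------------
# Independent oracle: direct subset enumeration with its own marginalization
# ---------------------------------------------------------------------------

def oracle_value(predict, x, S, points, weights):
    total = 0.0
    for b, w in zip(points, weights):
        z = b.copy()
        for j in S:
            z[j] = x[j]
        total += w * float(predict(z.reshape(1, -1))[0])
    return total


def oracle_shapley(predict, x, points, weights):
    p = len(x)
    phi = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [i for i in others if i != j]
        for size in range(p):
            for S in combinations(rest, size):
                wgt = factorial(size) * factorial(p - size - 1) / factorial(p)
                gain = (oracle_value(predict, x, set(S) | {j}, points, weights)
                        - oracle_value(predict, x, set(S), points, weights))
                phi[j] += wgt * gain
    return phi


def random_toy(p, seed, interaction=True):
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 2, p)
    c = float(rng.normal())
    if interaction and p >= 2:
        a = float(rng.normal())

        def fn(X):
            return X @ w + c + a * X[:, 0] * X[:, 1]
    else:
        def fn(X):
            return X @ w + c
    return toy_model(fn, p)


class TestCoalitionValue:
    def test_full_coalition_is_model_prediction(self):
        model = linear_model([2.0, -1.0])
        bg = Background.from_rows([[1.0, 1.0]])
        x = np.array([3.0, 5.0])
        assert coalition_value(model, x, [0, 1], bg) == pytest.approx(1.0)

    def test_empty_coalition_is_background_mean(self):
        model = linear_model([2.0, -1.0])
        bg = Background.from_rows([[1.0, 1.0], [3.0, 1.0]])
        assert coalition_value(model, np.array([9.0, 9.0]), [], bg) == pytest.approx(
            0.5 * (2 - 1) + 0.5 * (6 - 1))

    def test_partial_coalition_substitutes_from_background(self):
        # f(x1 from x, x2 from b) = 2*3 + (-1)*1 = 5
        model = linear_model([2.0, -1.0])
        bg = Background.from_rows([[1.0, 1.0]])
        assert coalition_value(model, np.array([3.0, 5.0]), [0], bg) == pytest.approx(5.0)

    def test_unknown_feature_rejected(self):
        model = linear_model([1.0, 1.0], names=["a", "b"])
        with pytest.raises(ContractError):
            coalition_value(model, np.zeros(2), ["z"], Background.from_rows([[0, 0]]))


class TestExactShapley:
    def test_two_feature_linear_closed_form(self):
        model = linear_model([2.0, -1.0])
        bg = Background.from_rows([[1.0, 1.0]])
        expl = exact_shapley(model, np.array([3.0, 5.0]), bg)
        assert expl.phi["x0"] == pytest.approx(4.0, abs=1e-10)
        assert expl.phi["x1"] == pytest.approx(-4.0, abs=1e-10)
        assert expl.base_value == pytest.approx(1.0, abs=1e-10)
        assert expl.prediction == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("p,seed", [(3, 0), (5, 1), (8, 2)])
    def test_matches_brute_force_oracle_on_random_toys(self, p, seed):
        rng = np.random.default_rng(seed + 100)
        model = random_toy(p, seed)
        x = rng.normal(size=p)
        pts = rng.normal(size=(4, p))
        w = rng.uniform(0.5, 1.5, 4)
        w /= w.sum()
        bg = Background(points=pts, weights=w, k=4)
        expl = exact_shapley(model, x, bg)
        oracle = oracle_shapley(model.estimator.predict, x, pts, w)
        assert np.allclose(expl.phi_array(model.feature_names), oracle, atol=1e-8)

    def test_efficiency_axiom(self):
        model = random_toy(6, 3)
        rng = np.random.default_rng(3)
        bg = Background.from_rows(rng.normal(size=(5, 6)))
        x = rng.normal(size=6)
        expl = exact_shapley(model, x, bg)
        fx = float(model.predict(x.reshape(1, -1))[0])
        assert expl.prediction == pytest.approx(fx, abs=1e-8)

    def test_dummy_axiom(self):
        # feature 2 never enters the model
        model = toy_model(lambda X: 3 * X[:, 0] - X[:, 1], 3)
        rng = np.random.default_rng(0)
        bg = Background.from_rows(rng.normal(size=(6, 3)))
        expl = exact_shapley(model, rng.normal(size=3), bg)
        assert expl.phi["x2"] == pytest.approx(0.0, abs=1e-10)

    def test_symmetry_axiom(self):
        model = toy_model(lambda X: X[:, 0] + X[:, 1] + 0.5 * X[:, 0] * X[:, 1], 2)
        bg = Background.from_rows([[0.0, 0.0]])
        expl = exact_shapley(model, np.array([2.0, 2.0]), bg)
        assert expl.phi["x0"] == pytest.approx(expl.phi["x1"], abs=1e-10)

    def test_additivity_axiom(self):
        rng = np.random.default_rng(9)
        wg, wh = rng.normal(size=4), rng.normal(size=4)
        g = linear_model(wg)
        h = toy_model(lambda X: X @ wh + X[:, 2] * X[:, 3], 4)
        fsum = toy_model(lambda X: X @ wg + X @ wh + X[:, 2] * X[:, 3], 4)
        bg = Background.from_rows(rng.normal(size=(5, 4)))
        x = rng.normal(size=4)
        pg = exact_shapley(g, x, bg).phi_array(g.feature_names)
        ph = exact_shapley(h, x, bg).phi_array(h.feature_names)
        pf = exact_shapley(fsum, x, bg).phi_array(fsum.feature_names)
        assert np.allclose(pf, pg + ph, atol=1e-8)

    def test_dimension_guard_directs_to_sampler(self):
        model = random_toy(6, 0)
        bg = Background.from_rows(np.zeros((2, 6)))
        with pytest.raises(ContractError, match="sampled_shapley"):
            exact_shapley(model, np.zeros(6), bg, p_limit=5)


class TestSampledShapley:
    def test_within_monte_carlo_tolerance_of_exact(self):
        rng = np.random.default_rng(4)
        model = random_toy(4, 4)
        x = rng.normal(size=4)
        bg = Background.from_rows(rng.normal(size=(6, 4)))
        exact = exact_shapley(model, x, bg)
        sampled = sampled_shapley(model, x, bg, n_samples=20_000, seed=0)
        for name in model.feature_names:
            tol = 3 * sampled.mc_stderr[name] + 1e-12
            assert abs(sampled.phi[name] - exact.phi[name]) <= tol

    def test_efficiency_holds_after_residual_redistribution(self):
        rng = np.random.default_rng(5)
        model = random_toy(5, 5)
        x = rng.normal(size=5)
        bg = Background.from_rows(rng.normal(size=(4, 5)))
        expl = sampled_shapley(model, x, bg, n_samples=200, seed=1)
        fx = coalition_value(model, x, list(range(5)), bg)
        assert expl.prediction == pytest.approx(fx, abs=1e-9)
        assert expl.metadata["residual_redistributed"] is True

    def test_stderr_shrinks_with_sample_size(self):
        # needs a 3-way nonlinearity: antithetic pairs cancel the sampling
        # variance of purely pairwise interactions exactly
        rng = np.random.default_rng(6)
        w = rng.normal(0, 2, 4)
        model = toy_model(lambda X: X @ w + 5 * np.tanh(X[:, 0] * X[:, 1] * X[:, 2]), 4)
        x = rng.normal(size=4)
        bg = Background.from_rows(rng.normal(size=(5, 4)))
        ratios = []
        for seed in range(8):
            s1 = sampled_shapley(model, x, bg, n_samples=400, seed=seed)
            s2 = sampled_shapley(model, x, bg, n_samples=800, seed=seed + 100)
            e1 = np.mean(list(s1.mc_stderr.values()))
            e2 = np.mean(list(s2.mc_stderr.values()))
            ratios.append(e2 / e1)
        assert np.mean(ratios) == pytest.approx(1 / np.sqrt(2), abs=0.15)

    def test_determinism(self):
        model = random_toy(4, 7)
        bg = Background.from_rows(np.random.default_rng(7).normal(size=(4, 4)))
        x = np.ones(4)
        a = sampled_shapley(model, x, bg, n_samples=100, seed=3)
        b = sampled_shapley(model, x, bg, n_samples=100, seed=3)
        assert a.phi == b.phi


class TestKmeansBackground:
    def test_k_equals_n_distinct_rows_returns_the_rows(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3)) * 10
        bg = kmeans_background(X, k=12, seed=0)
        got = set(map(tuple, np.round(bg.points, 6)))
        want = set(map(tuple, np.round(X, 6)))
        assert got == want
        assert np.allclose(bg.weights, 1 / 12)

    def test_k1_is_column_means(self):
        X = np.arange(12.0).reshape(4, 3)
        bg = kmeans_background(X, k=1, seed=0)
        assert np.allclose(bg.points[0], X.mean(axis=0))
        assert bg.weights.tolist() == [1.0]

    def test_determinism_and_weight_normalization(self):
        X = np.random.default_rng(1).normal(size=(40, 4))
        b1 = kmeans_background(X, k=5, seed=2)
        b2 = kmeans_background(X, k=5, seed=2)
        assert np.array_equal(b1.points, b2.points)
        assert b1.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_clusters_reproduce_full_background_for_linear_model(self):
        """With duplicated rows, 12 centroids represent the data exactly, so
        exact Shapley values agree with the full-data background to 1e-8."""
        rng = np.random.default_rng(3)
        base = rng.normal(size=(12, 3)) * 5
        X = np.repeat(base, 4, axis=0)
        model = linear_model(rng.normal(size=3))
        x = rng.normal(size=3)
        bg_k = kmeans_background(X, k=12, seed=0)
        bg_full = Background.from_rows(X)
        pk = exact_shapley(model, x, bg_k).phi_array(model.feature_names)
        pf = exact_shapley(model, x, bg_full).phi_array(model.feature_names)
        assert np.allclose(pk, pf, atol=1e-8)


class TestShapMatrix:
    def _table(self, X, names):
        df = pd.DataFrame(X, columns=names)
        df["Disintegration time [s]"] = 1.0 + np.arange(len(X))
        cats = {c: "descriptor" for c in names}
        cats["Disintegration time [s]"] = "target"
        return FormulationTable(df, cats)

    def test_constant_model_gives_all_zero_matrix(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        model = toy_model(lambda Z: np.full(len(Z), 42.0), 3)
        bg = Background.from_rows(X)
        m = shap_matrix(model, self._table(X, model.feature_names), bg)
        assert np.allclose(m.phi.to_numpy(), 0.0, atol=1e-10)

    def test_row_sums_plus_base_reproduce_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        model = random_toy(4, 11)
        bg = kmeans_background(X, k=4, seed=0)
        m = shap_matrix(model, self._table(X, model.feature_names), bg)
        recon = m.phi.sum(axis=1).to_numpy() + m.base_value
        assert np.allclose(recon, model.predict(X), atol=1e-8)

    def test_ranking_puts_dominant_feature_first(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 3))
        model = linear_model([10.0, 0.5, -0.5])
        bg = Background.from_rows(X)
        m = shap_matrix(model, self._table(X, model.feature_names), bg)
        assert m.ranking()[0][0] == "x0"


class TestPartialDependence:
    def test_additive_model_reproduces_component_up_to_constant(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-2, 2, size=(50, 2))
        model = toy_model(lambda Z: 2 * Z[:, 0] + Z[:, 1], 2)
        res = partial_dependence(model, X, ["x0"], grid=11)
        expected = 2 * res.grid[0] + X[:, 1].mean()
        assert np.allclose(res.values, expected, atol=1e-8)

    def test_centered_interaction_is_identically_flat(self):
        # f = x1*x2 with x2 = ±1 equally represented: marginal effect cancels
        x2 = np.array([-1.0, 1.0] * 10)
        X = np.column_stack([np.linspace(-3, 3, 20), x2])
        model = toy_model(lambda Z: Z[:, 0] * Z[:, 1], 2)
        res = partial_dependence(model, X, ["x0"], grid=9)
        assert np.allclose(res.values, 0.0, atol=1e-8)

    def test_constant_model_flat_everywhere(self):
        X = np.random.default_rng(1).normal(size=(20, 3))
        model = toy_model(lambda Z: np.full(len(Z), 7.0), 3)
        res = partial_dependence(model, X, ["x1", "x2"], grid=5)
        assert res.values.shape == (5, 5)
        assert np.allclose(res.values, 7.0, atol=1e-12)

    def test_two_feature_surface_matches_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(30, 3))
        model = toy_model(lambda Z: Z[:, 0] + 2 * Z[:, 1] + 3 * Z[:, 2], 3)
        res = partial_dependence(model, X, ["x0", "x1"], grid=4)
        g1, g2 = np.meshgrid(res.grid[0], res.grid[1], indexing="ij")
        assert np.allclose(res.values, g1 + 2 * g2 + 3 * X[:, 2].mean(), atol=1e-8)

    def test_more_than_two_features_rejected(self):
        model = random_toy(4, 0)
        with pytest.raises(ContractError):
            partial_dependence(model, np.zeros((5, 4)), ["x0", "x1", "x2"])
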