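"""Regressor zoo, cross-validation, multistart search, and stacked ensembles.

Six model families are exposed behind one uniform interface: random forests,
extremely randomized trees, gradient boosting, penalized linear models,
feedforward neural networks, and a stacked ensemble whose non-negative
least-squares meta-learner combines the out-of-fold predictions of its base
models. Estimator internals are delegated to scikit-learn; what this module
adds is the reproducible seeded randomized hyperparameter search
("multistart"), the out-of-fold evaluation protocol, and the leaderboard
bookkeeping.

Every stochastic step is driven by an explicit integer seed; fitting the same
spec to the same data twice yields bitwise-identical predictions.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ContractError
from .io import FormulationTable
from .metrics import CVPlan, EvaluationResult, evaluate

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "TrainedModel",
    "SearchBudget",
    "CVResult",
    "Leaderboard",
    "LeaderboardEntry",
    "fit",
    "cross_validate",
    "multistart_search",
    "stack_ensemble",
    "nnls_weights",
    "save_model",
    "load_model",
]

FAMILIES = (
    "random_forest",
    "extremely_randomized_trees",
    "gradient_boosting",
    "penalized_linear",
    "feedforward_net",
    "stacked_ensemble",
)


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus hyperparameters and a seed; fully reproducible."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ContractError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))

    def as_dict(self) -> dict:
        hp = {k: v for k, v in self.hyperparameters.items() if k != "base_specs"}
        if "base_specs" in self.hyperparameters:
            hp["base_specs"] = [s.as_dict() for s in self.hyperparameters["base_specs"]]
        return {"family": self.family, "hyperparameters": hp, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        hp = dict(d.get("hyperparameters", {}))
        if "base_specs" in hp:
            hp["base_specs"] = [cls.from_dict(s) for s in hp["base_specs"]]
        return cls(family=d["family"], hyperparameters=hp, seed=int(d.get("seed", 0)))


@dataclass
class TrainedModel:
    """A fitted regressor bound to an ordered feature-name list."""

    spec: ModelSpec
    feature_names: list[str]
    estimator: object
    training_metadata: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        """Predict disintegration times; X is an array (feature order fixed)
        or a DataFrame (columns looked up by name)."""
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ContractError(f"missing feature column(s): {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != len(self.feature_names):
            raise ContractError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return np.asarray(self.estimator.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = int(spec.seed)
    fam = spec.family
    if fam == "random_forest":
        return RandomForestRegressor(
            n_estimators=int(hp.get("n_estimators", 200)),
            max_features=hp.get("max_features", 0.7),
            min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
            random_state=seed,
            n_jobs=1,
        )
    if fam == "extremely_randomized_trees":
        return ExtraTreesRegressor(
            n_estimators=int(hp.get("n_estimators", 200)),
            max_features=hp.get("max_features", 0.7),
            min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
            random_state=seed,
            n_jobs=1,
        )
    if fam == "gradient_boosting":
        return GradientBoostingRegressor(
            n_estimators=int(hp.get("n_estimators", 300)),
            learning_rate=float(hp.get("learning_rate", 0.05)),
            max_depth=int(hp.get("max_depth", 3)),
            subsample=float(hp.get("subsample", 0.9)),
            random_state=seed,
        )
    if fam == "penalized_linear":
        return make_pipeline(
            StandardScaler(),
            ElasticNet(
                alpha=float(hp.get("alpha", 1e-3)),
                l1_ratio=float(hp.get("l1_ratio", 0.5)),
                max_iter=int(hp.get("max_iter", 20000)),
                random_state=seed,
            ),
        )
    if fam == "feedforward_net":
        # Rectifier (relu) hidden units; L2 penalty stands in for dropout
        # regularization. Default topology: two 100-neuron hidden layers.
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=tuple(hp.get("hidden", (100, 100))),
                activation="relu",
                alpha=float(hp.get("alpha", 1e-3)),
                learning_rate_init=float(hp.get("learning_rate_init", 1e-3)),
                max_iter=int(hp.get("max_iter", 400)),
                early_stopping=bool(hp.get("early_stopping", True)),
                validation_fraction=float(hp.get("validation_fraction", 0.1)),
                n_iter_no_change=int(hp.get("n_iter_no_change", 20)),
                random_state=seed,
            ),
        )
    raise ContractError(f"family {fam!r} has no direct estimator")


def _iterations_used(estimator) -> int | None:
    est = estimator
    if hasattr(est, "steps"):
        est = est.steps[-1][1]
    for attr in ("n_iter_", "n_estimators_", "n_estimators"):
        if hasattr(est, attr):
            val = getattr(est, attr)
            return int(np.atleast_1d(val)[0]) if not np.isscalar(val) else int(val)
    return None


def fit(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one model spec. Missing values are refused, never imputed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] < 2:
        raise ContractError(f"need a 2-D X with |y| = rows(X) >= 2, got {X.shape}, {y.shape}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ContractError("missing/non-finite values in training data; imputation is not performed")
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ContractError("feature_names length does not match X")

    metadata: dict = {}
    if float(np.std(y)) == 0.0:
        metadata["constant_target"] = True

    if spec.family == "stacked_ensemble":
        return _fit_stacked(spec, X, y, names, metadata)

    estimator = _build_estimator(spec)
    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(X, y)
    metadata["fit_seconds"] = time.perf_counter() - t0
    it = _iterations_used(estimator)
    if it is not None:
        metadata["iterations"] = it
    return TrainedModel(spec=spec, feature_names=names, estimator=estimator,
                        training_metadata=metadata)


# ---------------------------------------------------------------------------
# Stacked ensemble
# ---------------------------------------------------------------------------

def nnls_weights(P: np.ndarray, y: np.ndarray, intercept: bool = True
                 ) -> tuple[np.ndarray, float]:
    """Non-negative least squares ``y ≈ P·w + c`` with w ≥ 0, free intercept.

    Exactly duplicated base-prediction columns receive equal shares of the
    weight a single copy would get (symmetry tie rule).
    """
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    if P.ndim != 2 or P.shape[0] != y.size:
        raise ContractError("base prediction matrix not aligned with y")
    m = P.shape[1]
    if m < 2:
        raise ContractError("stacking requires at least 2 base models")

    # group exactly-identical columns
    keys: dict[bytes, list[int]] = {}
    for j in range(m):
        keys.setdefault(P[:, j].tobytes(), []).append(j)
    groups = list(keys.values())
    Pu = P[:, [g[0] for g in groups]]

    if intercept:
        A = np.hstack([Pu, np.ones((P.shape[0], 1))])
        lb = np.r_[np.zeros(Pu.shape[1]), -np.inf]
        ub = np.full(Pu.shape[1] + 1, np.inf)
    else:
        A = Pu
        lb = np.zeros(Pu.shape[1])
        ub = np.full(Pu.shape[1], np.inf)
    sol = lsq_linear(A, y, bounds=(lb, ub), method="bvls" if A.shape[1] <= A.shape[0] else "trf")
    w_u = sol.x[: Pu.shape[1]]
    c = float(sol.x[-1]) if intercept else 0.0

    w = np.zeros(m)
    for g, wg in zip(groups, w_u):
        for j in g:
            w[j] = wg / len(g)
    return w, c


class _StackedRegressor:
    """Predicts by refit base models combined with fixed NNLS weights."""

    def __init__(self, base_models: list[TrainedModel], weights: np.ndarray, intercept: float):
        self.base_models = base_models
        self.weights = np.asarray(weights, dtype=float)
        self.intercept = float(intercept)

    def predict(self, X) -> np.ndarray:
        P = np.column_stack([m.predict(X) for m in self.base_models])
        return P @ self.weights + self.intercept


def _fit_stacked(spec: ModelSpec, X, y, names, metadata) -> TrainedModel:
    base_specs = spec.hyperparameters.get("base_specs")
    if not base_specs or len(base_specs) < 2:
        raise ContractError("stacked_ensemble requires >= 2 base_specs")
    k = int(spec.hyperparameters.get("n_internal_folds", 5))
    from .metrics import balanced_kfold  # avoid cycle at import time

    plan = balanced_kfold(y, k=min(k, len(y)), seed=spec.seed, n_bins=min(10, len(y)))
    folds = plan.fold_indices([str(i) for i in range(len(y))])
    P = np.empty((len(y), len(base_specs)))
    for b, bspec in enumerate(base_specs):
        for f in range(1, plan.k + 1):
            test = folds == f
            model = fit(bspec, X[~test], y[~test], names)
            P[test, b] = model.predict(X[test])
    w, c = nnls_weights(P, y, intercept=True)
    bases = [fit(bspec, X, y, names) for bspec in base_specs]
    metadata.update({"meta_weights": w.tolist(), "meta_intercept": c,
                     "iterations": plan.k * len(base_specs)})
    return TrainedModel(spec=spec, feature_names=names,
                        estimator=_StackedRegressor(bases, w, c),
                        training_metadata=metadata)


def stack_ensemble(base_oof: np.ndarray, y: np.ndarray,
                   base_models: Sequence[TrainedModel] | None = None,
                   base_names: Sequence[str] | None = None) -> TrainedModel:
    """Combine base models' out-of-fold predictions with an NNLS meta-learner.

    ``base_oof`` is (n_records × n_base_models) with each column a base
    model's out-of-fold predictions aligned to ``y``. If ``base_models`` are
    given, the returned model predicts from raw features via the weighted
    bases; otherwise it predicts from a matrix of base predictions.
    """
    P = np.asarray(base_oof, dtype=float)
    w, c = nnls_weights(P, y, intercept=True)
    meta = {"meta_weights": w.tolist(), "meta_intercept": c}
    spec = ModelSpec("stacked_ensemble", {"n_base_models": P.shape[1]}, seed=0)
    if base_models is not None:
        if len(base_models) != P.shape[1]:
            raise ContractError("base_models length does not match base_oof columns")
        return TrainedModel(spec=spec, feature_names=list(base_models[0].feature_names),
                            estimator=_StackedRegressor(list(base_models), w, c),
                            training_metadata=meta)

    names = list(base_names) if base_names else [f"base{j}" for j in range(P.shape[1])]

    class _Linear:
        def predict(self, Z):
            return np.asarray(Z, dtype=float) @ w + c

    return TrainedModel(spec=spec, feature_names=names, estimator=_Linear(),
                        training_metadata=meta)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold and pooled out-of-fold evaluation of one model spec."""

    spec: ModelSpec
    per_fold: list[EvaluationResult]
    pooled: EvaluationResult
    oof_pred: np.ndarray
    fold_of: np.ndarray
    models: list[TrainedModel] = field(default_factory=list)

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = np.array([getattr(r, metric) for r in self.per_fold])
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def cross_validate(
    spec: ModelSpec,
    table: FormulationTable,
    plan: CVPlan,
    feature_columns: Sequence[str] | None = None,
    keep_models: bool = True,
) -> CVResult:
    """K-fold out-of-fold evaluation: each record is predicted exactly once,
    by a model whose training folds excluded it. Pooled metrics are computed
    on the concatenated out-of-fold predictions."""
    cols = list(feature_columns) if feature_columns is not None else table.feature_columns
    X = table.X(cols)
    y = table.y
    folds = plan.fold_indices(table.record_ids)
    oof = np.full(len(y), np.nan)
    per_fold: list[EvaluationResult] = []
    models: list[TrainedModel] = []
    for f in range(1, plan.k + 1):
        test = folds == f
        if (~test).sum() < 2:
            raise ContractError(f"fold {f}: fewer than 2 training records")
        seeded = ModelSpec(spec.family, spec.hyperparameters, seed=spec.seed)
        model = fit(seeded, X[~test], y[~test], cols)
        oof[test] = model.predict(X[test])
        per_fold.append(evaluate(y[test], oof[test]))
        if keep_models:
            models.append(model)
    pooled = evaluate(y, oof)
    return CVResult(spec=spec, per_fold=per_fold, pooled=pooled, oof_pred=oof,
                    fold_of=folds, models=models)


# ---------------------------------------------------------------------------
# Multistart randomized search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchBudget:
    """Per-start caps. ``max_iterations`` bounds trees/epochs (hardware-
    independent default); ``max_time_s`` optionally bounds per-start wall
    clock, mirroring loop-time-capped AutoML runs."""

    max_iterations: int | None = None
    max_time_s: float | None = None


def _sample_hyperparameters(family: str, rng: np.random.Generator,
                            budget: SearchBudget) -> dict:
    cap = budget.max_iterations

    def it(lo, hi):
        n = int(rng.integers(lo, hi + 1))
        return min(n, cap) if cap else n

    if family in ("random_forest", "extremely_randomized_trees"):
        return {
            "n_estimators": it(100, 400),
            "max_features": float(rng.uniform(0.3, 1.0)),
            "min_samples_leaf": int(rng.integers(1, 6)),
        }
    if family == "gradient_boosting":
        return {
            "n_estimators": it(100, 500),
            "learning_rate": float(10 ** rng.uniform(-2.0, -0.5)),
            "max_depth": int(rng.integers(2, 7)),
            "subsample": float(rng.uniform(0.7, 1.0)),
        }
    if family == "penalized_linear":
        return {
            "alpha": float(10 ** rng.uniform(-4, 1)),
            "l1_ratio": float(rng.uniform(0.0, 1.0)),
        }
    if family == "feedforward_net":
        hidden = [(100, 100), (100,), (50, 50)][int(rng.integers(3))]
        return {
            "hidden": hidden,
            "alpha": float(10 ** rng.uniform(-4, -1)),
            "learning_rate_init": float(10 ** rng.uniform(-3.5, -2)),
            "max_iter": min(400, cap) if cap else 400,
        }
    raise ContractError(f"cannot sample hyperparameters for family {family!r}")


@dataclass
class LeaderboardEntry:
    spec: ModelSpec
    per_fold: list[EvaluationResult]
    pooled: EvaluationResult
    mean_rmse: float
    sd_rmse: float
    mean_nrmse: float
    sd_nrmse: float
    mean_r2: float
    sd_r2: float


@dataclass
class Leaderboard:
    """Model-search results sorted by ascending mean out-of-fold RMSE."""

    entries: list[LeaderboardEntry]

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.entries.sort(key=lambda e: (e.mean_rmse, e.pooled.rmse, repr(e.spec.as_dict())))

    @property
    def best(self) -> LeaderboardEntry:
        return self.entries[0]

    def summary(self) -> dict[str, float]:
        """Dispersion across starts: mean and SD of each pooled metric
        (multistart robustness report)."""
        out: dict[str, float] = {"n_entries": len(self.entries)}
        for metric in ("rmse", "nrmse", "r2"):
            vals = np.array([getattr(e.pooled, metric) for e in self.entries])
            out[f"mean_{metric}"] = float(vals.mean())
            out[f"sd_{metric}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, e in enumerate(self.entries, 1):
            rows.append({
                "rank": rank,
                "family": e.spec.family,
                "seed": e.spec.seed,
                "mean_rmse": e.mean_rmse, "sd_rmse": e.sd_rmse,
                "mean_nrmse": e.mean_nrmse, "sd_nrmse": e.sd_nrmse,
                "mean_r2": e.mean_r2, "sd_r2": e.sd_r2,
                "pooled_rmse": e.pooled.rmse, "pooled_nrmse": e.pooled.nrmse,
                "pooled_r2": e.pooled.r2,
                "hyperparameters": json.dumps(e.spec.as_dict()["hyperparameters"]),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _entry_from_cv(cv: CVResult) -> LeaderboardEntry:
    mr, sr = cv.mean_sd("rmse")
    mn, sn = cv.mean_sd("nrmse")
    m2, s2 = cv.mean_sd("r2")
    return LeaderboardEntry(spec=cv.spec, per_fold=cv.per_fold, pooled=cv.pooled,
                            mean_rmse=mr, sd_rmse=sr, mean_nrmse=mn, sd_nrmse=sn,
                            mean_r2=m2, sd_r2=s2)


def multistart_search(
    families: Sequence[str],
    table: FormulationTable,
    plan: CVPlan,
    n_starts: int = 5,
    budget: SearchBudget = SearchBudget(),
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
    include_stacked: bool = False,
) -> Leaderboard:
    """Seeded randomized hyperparameter search: ``n_starts`` independent
    draws per family, each evaluated by k-fold cross-validation on ``plan``.

    With ``include_stacked``, a stacked ensemble of the best spec per family
    (NNLS on their out-of-fold predictions) is appended and evaluated too.
    """
    if not families:
        raise ContractError("empty family list")
    if n_starts < 1:
        raise ContractError("n_starts must be >= 1")
    unknown = [f for f in families if f not in FAMILIES or f == "stacked_ensemble"]
    if unknown:
        raise ContractError(f"cannot search families {unknown}; use include_stacked for stacking")

    entries: list[LeaderboardEntry] = []
    cv_by_spec: dict[int, CVResult] = {}
    ss = np.random.SeedSequence(seed)
    for fi, family in enumerate(families):
        for start in range(n_starts):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(fi, start))
            sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            rng = np.random.default_rng(child)
            t0 = time.perf_counter()
            hp = _sample_hyperparameters(family, rng, budget)
            spec = ModelSpec(family, hp, seed=sub_seed)
            cv = cross_validate(spec, table, plan, feature_columns, keep_models=False)
            entries.append(_entry_from_cv(cv))
            cv_by_spec[id(entries[-1])] = cv
            if budget.max_time_s and (time.perf_counter() - t0) > budget.max_time_s:
                break  # per-start time cap exhausted for this family

    if include_stacked and len(families) >= 2:
        best_per_family: dict[str, tuple[LeaderboardEntry, CVResult]] = {}
        for e in entries:
            cur = best_per_family.get(e.spec.family)
            if cur is None or e.mean_rmse < cur[0].mean_rmse:
                best_per_family[e.spec.family] = (e, cv_by_spec[id(e)])
        base = list(best_per_family.values())
        stack_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        spec = ModelSpec("stacked_ensemble",
                         {"base_specs": [e.spec for e, _ in base]}, seed=stack_seed)
        cv = cross_validate(spec, table, plan, feature_columns, keep_models=False)
        entries.append(_entry_from_cv(cv))

    return Leaderboard(entries=entries)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory: str | Path,
               extra_manifest: Mapping | None = None) -> Path:
    """Serialize a trained model as ``manifest.json`` + ``weights.joblib``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "spec": model.spec.as_dict(),
        "feature_names": model.feature_names,
        "training_metadata": {k: v for k, v in model.training_metadata.items()
                              if isinstance(v, (int, float, str, bool, list))},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    joblib.dump(model.estimator, directory / "weights.joblib")
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    estimator = joblib.load(directory / "weights.joblib")
    return TrainedModel(
        spec=ModelSpec.from_dict(manifest["spec"]),
        feature_names=list(manifest["feature_names"]),
        estimator=estimator,
        training_metadata=dict(manifest.get("training_metadata", {})),
    )
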