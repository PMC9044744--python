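"""High-level modelling interface: ``DisintegrationModel`` → ``fit()`` →
``DisintegrationResults``.

This is the front door of the package: build a model object from a
(preprocessed, descriptor-enriched) formulation table, optionally run the
repeated-CV feature-selection loop, then ``fit()`` to run the multistart
randomized model search under 10-fold cross-validation. The returned results
object carries the leaderboard, the pooled out-of-fold metrics, a
deployment model refit on all records, and hangs the explanation layer
(Shapley matrix, partial dependence) and prediction off the fitted state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .explain import Background, PDPResult, ShapMatrix, kmeans_background, partial_dependence, shap_matrix
from .io import ColumnRegistry, FormulationTable, read_formulation_table
from .metrics import CVPlan, EvaluationResult, balanced_kfold, nrmse
from .models import (
    CVResult,
    Leaderboard,
    ModelSpec,
    SearchBudget,
    TrainedModel,
    cross_validate,
    fit as fit_spec,
    multistart_search,
    save_model,
)
from .selection import ImportanceTable, SelectedFeatures, feature_selection_loop

__all__ = ["DisintegrationModel", "DisintegrationResults"]

_DEFAULT_FAMILIES = ("gradient_boosting", "random_forest", "penalized_linear")


class DisintegrationModel:
    """Disintegration-time model over a formulation table.

    Parameters
    ----------
    table : FormulationTable
        Preprocessed table (filtered, descriptor-enriched). All composition,
        manufacturing and descriptor columns are candidate inputs.
    families : sequence of str
        Model families searched during fitting.

    Examples
    --------
    >>> from odtpredict.synthetic import GeneratorConfig, generate_dataset
    >>> table, truth, _ = generate_dataset(GeneratorConfig(n=120, seed=7))
    >>> model = DisintegrationModel(table)
    >>> res = model.fit(k=5, n_starts=1, seed=7)
    >>> 0.0 <= res.nrmse  # doctest: +SKIP
    """

    def __init__(self, table: FormulationTable,
                 families: Sequence[str] = _DEFAULT_FAMILIES):
        if table.n < 4:
            raise ContractError("need at least 4 records to model")
        self.table = table
        self.families = tuple(families)
        self.selected: SelectedFeatures | None = None
        self.importance: ImportanceTable | None = None

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, categories: dict[str, str],
                       families: Sequence[str] = _DEFAULT_FAMILIES) -> "DisintegrationModel":
        return cls(FormulationTable(df.reset_index(drop=True), dict(categories)), families)

    @classmethod
    def from_csv(cls, path: str | Path, registry: ColumnRegistry | None = None,
                 families: Sequence[str] = _DEFAULT_FAMILIES) -> "DisintegrationModel":
        return cls(read_formulation_table(path, registry), families)

    # -- feature selection --------------------------------------------------
    @property
    def feature_columns(self) -> list[str]:
        if self.selected is not None:
            return list(self.selected.names)
        return self.table.feature_columns

    def select_features(self, n_loops: int = 25, k: int = 5, threshold: float = 0.1,
                        seed: int = 0, budget: SearchBudget = SearchBudget(),
                        n_starts: int = 1, families: Sequence[str] | None = None,
                        **kwargs) -> SelectedFeatures:
        """Run the repeated-CV permutation-importance loop and pin the
        selected input vector on this model object."""
        selected, importance = feature_selection_loop(
            self.table, families=families or self.families, n_loops=n_loops, k=k,
            budget=budget, n_starts=n_starts, threshold=threshold, seed=seed, **kwargs)
        self.selected = selected
        self.importance = importance
        return selected

    # -- fitting ------------------------------------------------------------
    def fit(self, k: int = 10, n_starts: int = 5, seed: int = 0,
            budget: SearchBudget = SearchBudget(), include_stacked: bool = False,
            n_bins: int = 10) -> "DisintegrationResults":
        """Multistart randomized search under balanced k-fold CV.

        The best spec by mean out-of-fold RMSE is re-reported with its pooled
        metrics and refit on all records as the deployment model.
        """
        plan = balanced_kfold(self.table, k=k, seed=seed, n_bins=n_bins)
        cols = self.feature_columns
        board = multistart_search(self.families, self.table, plan, n_starts=n_starts,
                                  budget=budget, seed=seed, feature_columns=cols,
                                  include_stacked=include_stacked)
        best = board.best.spec
        cv = cross_validate(best, self.table, plan, feature_columns=cols)
        final = fit_spec(best, self.table.X(cols), self.table.y, cols)
        return DisintegrationResults(model=self, plan=plan, leaderboard=board,
                                     best_spec=best, cv=cv, final_model=final)


@dataclass
class DisintegrationResults:
    """Fitted state: leaderboard, out-of-fold metrics, deployment model."""

    model: DisintegrationModel
    plan: CVPlan
    leaderboard: Leaderboard
    best_spec: ModelSpec
    cv: CVResult
    final_model: TrainedModel
    _background: Background | None = field(default=None, repr=False)

    # -- metrics ------------------------------------------------------------
    @property
    def pooled(self) -> EvaluationResult:
        return self.cv.pooled

    @property
    def rmse(self) -> float:
        return self.cv.pooled.rmse

    @property
    def nrmse(self) -> float:
        return self.cv.pooled.nrmse

    @property
    def r2(self) -> float:
        return self.cv.pooled.r2

    @property
    def oof_predictions(self) -> np.ndarray:
        """Out-of-fold predictions aligned with the table's records."""
        return self.cv.oof_pred

    def summary(self) -> str:
        """Plain-text results table (pooled out-of-fold metrics, per-fold
        dispersion, multistart dispersion)."""
        t = self.model.table
        mr, sr = self.cv.mean_sd("rmse")
        mn, sn = self.cv.mean_sd("nrmse")
        m2, s2 = self.cv.mean_sd("r2")
        ms = self.leaderboard.summary()
        width = 64
        lines = [
            "ODT Disintegration-Time Model Results".center(width),
            "=" * width,
            f"{'No. records:':<28}{t.n:>8}    {'CV folds:':<12}{self.plan.k:>4}",
            f"{'Input features:':<28}{len(self.final_model.feature_names):>8}    "
            f"{'Search starts:':<12}{ms['n_entries']:>4}",
            f"{'Best family:':<28}{self.best_spec.family:>24}",
            "-" * width,
            f"{'Pooled out-of-fold:':<22}RMSE {self.rmse:8.3f} s   "
            f"NRMSE {self.nrmse:6.2f} %   R2 {self.r2:6.3f}",
            f"{'Per-fold mean (SD):':<22}RMSE {mr:8.3f} ({sr:.3f})   "
            f"NRMSE {mn:6.2f} ({sn:.2f})   R2 {m2:6.3f} ({s2:.3f})",
            f"{'Multistart mean (SD):':<22}RMSE {ms['mean_rmse']:8.3f} ({ms['sd_rmse']:.3f})   "
            f"NRMSE {ms['mean_nrmse']:6.2f} ({ms['sd_nrmse']:.2f})",
            "=" * width,
        ]
        return "\n".join(lines)

    # -- prediction ---------------------------------------------------------
    def predict(self, rows: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predict disintegration times [s] with the deployment model (the
        best spec refit on all records; out-of-fold predictions are kept
        separately in ``oof_predictions``)."""
        return self.final_model.predict(rows)

    # -- explanation --------------------------------------------------------
    def background(self, k: int = 12, seed: int = 0) -> Background:
        """Weighted k-means summary (default 12 centroids) of the training
        feature matrix, cached for reuse across explanations."""
        if self._background is None or self._background.k != k:
            X = self.model.table.X(self.final_model.feature_names)
            k_eff = min(k, X.shape[0])
            self._background = kmeans_background(X, k=k_eff, seed=seed,
                                                 feature_names=self.final_model.feature_names)
        return self._background

    def shap_values(self, estimator: str = "auto", n_samples: int = 2000,
                    seed: int = 0, k_background: int = 12,
                    max_records: int | None = None) -> ShapMatrix:
        """Shapley attribution matrix for (a subset of) the table's records."""
        table = self.model.table
        if max_records is not None and table.n > max_records:
            sub = table.data.iloc[:max_records].reset_index(drop=True)
            table = FormulationTable(sub, dict(table.categories))
        return shap_matrix(self.final_model, table, self.background(k_background, seed),
                           estimator=estimator, n_samples=n_samples, seed=seed)

    def partial_dependence(self, S: Sequence[str], grid: int | Sequence = 20,
                           percentiles=None) -> PDPResult:
        """Partial dependence of the deployment model on 1–2 features."""
        return partial_dependence(self.final_model, self.model.table, S,
                                  grid=grid, percentiles=percentiles)

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        """Write the deployment model bundle plus metrics and leaderboard."""
        directory = Path(directory)
        extra = {
            "metrics": self.pooled.as_dict(),
            "k_folds": self.plan.k,
            "cv_seed": self.plan.seed,
        }
        save_model(self.final_model, directory, extra_manifest=extra)
        self.leaderboard.to_csv(directory / "leaderboard.csv")
        self.plan.to_csv(directory / "cv_plan.csv")
        return directory
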