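"""Repeated-CV permutation-importance feature selection.

The input vector for the final disintegration-time model is chosen by a
short-loop procedure: in each of ``n_loops`` repetitions a fresh seeded
5-fold plan is drawn, a best-of-budget model is found by a small randomized
search, and a model-agnostic permutation importance is measured on the
out-of-fold data — the mean increase in out-of-fold RMSE when one feature
column is permuted, floored at zero. Raw importances are scaled per loop by
their maximum (so the top feature scores 1), averaged across loops, and
features whose aggregated scaled importance reaches the threshold
(inclusive, default 0.1) form the selected input vector.

Permutation importance is used for every model family alike: it needs only a
predict function, so tree ensembles, linear models and neural networks are
ranked on the same footing, and it can be validated against synthetic ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, SelectionError
from .io import FormulationTable
from .metrics import CVPlan, balanced_kfold, rmse
from .models import (
    CVResult,
    ModelSpec,
    SearchBudget,
    TrainedModel,
    cross_validate,
    fit,
    multistart_search,
)

__all__ = [
    "ImportanceTable",
    "SelectedFeatures",
    "variable_importance",
    "scale_importance",
    "apply_threshold",
    "feature_selection_loop",
]


@dataclass
class ImportanceTable:
    """Per-feature raw and scaled (max-normalized) variable importances."""

    raw: dict[str, float]
    scaled: dict[str, float]
    category: dict[str, str] = field(default_factory=dict)
    n_loops_aggregated: int = 1

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.scaled.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Variable": name,
                "Variable Type": self.category.get(name, ""),
                "Scaled Variable Importance": scaled,
                "Raw Importance": self.raw.get(name, float("nan")),
            }
            for name, scaled in self.ranked()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SelectedFeatures:
    """The thresholded input vector plus the provenance needed to re-run."""

    names: list[str]
    threshold: float
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"names": self.names, "threshold": self.threshold, "provenance": self.provenance},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectedFeatures":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(names=list(d["names"]), threshold=float(d["threshold"]),
                   provenance=dict(d.get("provenance", {})))


def variable_importance(
    model_or_spec: TrainedModel | ModelSpec,
    table: FormulationTable,
    plan: CVPlan | None = None,
    n_permutations: int = 3,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
    _identity: bool = False,
) -> ImportanceTable:
    """Permutation importance on out-of-fold data.

    For each fold of ``plan``, the model (refit on the training part using
    the spec of ``model_or_spec``) predicts the held-out records; the
    importance of feature j is the mean increase of held-out RMSE over
    ``n_permutations`` seeded shuffles of column j, floored at 0. Without a
    plan the importance is measured in-sample with the already-trained model.
    """
    if n_permutations < 1:
        raise ContractError("n_permutations must be >= 1")
    spec = model_or_spec.spec if isinstance(model_or_spec, TrainedModel) else model_or_spec
    cols = list(feature_columns) if feature_columns is not None else table.feature_columns
    X = table.X(cols)
    y = table.y
    rng = np.random.default_rng(seed)

    if plan is not None:
        folds = plan.fold_indices(table.record_ids)
        fold_ids = range(1, plan.k + 1)
        models = {}
        for f in fold_ids:
            test = folds == f
            models[f] = fit(spec, X[~test], y[~test], cols)
        eval_sets = [(models[f], folds == f) for f in fold_ids]
    else:
        if not isinstance(model_or_spec, TrainedModel):
            raise ContractError("without a CV plan, a TrainedModel is required")
        eval_sets = [(model_or_spec, np.ones(len(y), dtype=bool))]

    raw = {c: 0.0 for c in cols}
    n_terms = 0
    for model, mask in eval_sets:
        Xt, yt = X[mask], y[mask]
        base = rmse(yt, model.predict(Xt))
        for _ in range(n_permutations):
            for j, c in enumerate(cols):
                perm = np.arange(len(yt)) if _identity else rng.permutation(len(yt))
                Xp = Xt.copy()
                Xp[:, j] = Xt[perm, j]
                raw[c] += rmse(yt, model.predict(Xp)) - base
        n_terms += n_permutations
    raw = {c: max(0.0, v / n_terms) for c, v in raw.items()}
    category = {c: table.categories.get(c, "") for c in cols}
    table_out = ImportanceTable(raw=raw, scaled=dict(raw), category=category)
    return scale_importance(table_out)


def scale_importance(imp: ImportanceTable) -> ImportanceTable:
    """Scale raw importances by their maximum; all-zero stays all-zero."""
    mx = max(imp.raw.values()) if imp.raw else 0.0
    scaled = {c: (v / mx if mx > 0 else 0.0) for c, v in imp.raw.items()}
    return ImportanceTable(raw=dict(imp.raw), scaled=scaled,
                           category=dict(imp.category),
                           n_loops_aggregated=imp.n_loops_aggregated)


def apply_threshold(imp: ImportanceTable, threshold: float) -> list[str]:
    """Features whose scaled importance reaches ``threshold`` (inclusive),
    in descending-importance order. Monotone: a higher threshold selects a
    subset of a lower one."""
    return [c for c, v in imp.ranked() if v >= threshold]


def feature_selection_loop(
    table: FormulationTable,
    families: Sequence[str] = ("gradient_boosting",),
    n_loops: int = 25,
    k: int = 5,
    budget: SearchBudget = SearchBudget(),
    n_starts: int = 1,
    threshold: float = 0.1,
    seed: int = 0,
    n_permutations: int = 2,
    n_bins: int = 10,
    feature_columns: Sequence[str] | None = None,
    aggregate: str = "mean",
) -> tuple[SelectedFeatures, ImportanceTable]:
    """Short-loop feature selection repeated over fresh CV plans.

    Each loop draws a fresh seeded ``k``-fold plan, picks the best of a small
    randomized search (``n_starts`` per family within ``budget``), computes
    scaled permutation importances on the out-of-fold data, and the
    per-feature scaled importances are aggregated (mean by default, median
    optional) over loops. Features with aggregated importance ≥ ``threshold``
    are selected; an empty selection raises :class:`SelectionError`.
    """
    if n_loops < 1:
        raise ContractError("n_loops must be >= 1")
    if aggregate not in ("mean", "median"):
        raise ContractError("aggregate must be 'mean' or 'median'")
    cols = list(feature_columns) if feature_columns is not None else table.feature_columns
    per_loop: list[dict[str, float]] = []
    loop_seeds: list[int] = []
    for loop in range(n_loops):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(loop,))
        loop_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        loop_seeds.append(loop_seed)
        plan = balanced_kfold(table, k=k, seed=loop_seed, n_bins=n_bins)
        board = multistart_search(families, table, plan, n_starts=n_starts,
                                  budget=budget, seed=loop_seed, feature_columns=cols)
        imp = variable_importance(board.best.spec, table, plan,
                                  n_permutations=n_permutations, seed=loop_seed,
                                  feature_columns=cols)
        per_loop.append(imp.scaled)

    agg_fn = np.mean if aggregate == "mean" else np.median
    aggregated = {c: float(agg_fn([d[c] for d in per_loop])) for c in cols}
    category = {c: table.categories.get(c, "") for c in cols}
    # rescale the aggregate so the top-ranked feature reads 1.0 again
    imp_table = scale_importance(
        ImportanceTable(raw=aggregated, scaled=dict(aggregated), category=category,
                        n_loops_aggregated=n_loops)
    )
    selected = apply_threshold(imp_table, threshold)
    if not selected:
        raise SelectionError(
            f"zero features reach the importance threshold {threshold}; lower the threshold"
        )
    provenance = {
        "seed": seed, "loop_seeds": loop_seeds, "n_loops": n_loops, "k": k,
        "families": list(families), "n_starts": n_starts,
        "n_permutations": n_permutations, "aggregate": aggregate,
    }
    return SelectedFeatures(names=selected, threshold=threshold, provenance=provenance), imp_table
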