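"""Error metrics and the distribution-balanced k-fold splitter.

Three metrics are reported throughout, all defined on observed/predicted
disintegration times in seconds:

* RMSE, the root mean squared error;
* NRMSE, the RMSE normalized by the observed target range
  (``obs_max − obs_min``) and expressed as a percent — scale-free, so models
  fitted to databases with different time ranges are comparable;
* R², the coefficient of determination ``1 − SS_res / SS_tot`` (may be
  negative for models worse than the mean predictor).

Because the disintegration-time distribution is right-skewed, plain random
k-fold splits can concentrate slow-disintegrating tablets in a few folds.
:func:`balanced_kfold` stratifies on target quantiles so every fold sees the
same target distribution, while keeping fold sizes within one record of each
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError

__all__ = [
    "PredictionPair",
    "EvaluationResult",
    "CVPlan",
    "rmse",
    "nrmse",
    "r2",
    "evaluate",
    "balanced_kfold",
]


@dataclass(frozen=True)
class PredictionPair:
    """Aligned vectors of observed and predicted targets (seconds)."""

    obs: np.ndarray
    pred: np.ndarray

    def __post_init__(self) -> None:
        obs = np.asarray(self.obs, dtype=float)
        pred = np.asarray(self.pred, dtype=float)
        if obs.ndim != 1 or pred.ndim != 1 or obs.shape != pred.shape:
            raise ContractError(f"obs/pred must be equal-length vectors, got {obs.shape} vs {pred.shape}")
        if obs.size < 1:
            raise ContractError("need at least one observation")
        object.__setattr__(self, "obs", obs)
        object.__setattr__(self, "pred", pred)

    @property
    def n(self) -> int:
        return int(self.obs.size)


@dataclass(frozen=True)
class EvaluationResult:
    """RMSE [s], NRMSE [%], and R² for one prediction set."""

    rmse: float
    nrmse: float
    r2: float

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "nrmse": self.nrmse, "r2": self.r2}


def _pair(pair_or_obs, pred=None) -> PredictionPair:
    if isinstance(pair_or_obs, PredictionPair):
        return pair_or_obs
    return PredictionPair(np.asarray(pair_or_obs), np.asarray(pred))


def rmse(pair_or_obs, pred=None) -> float:
    """Root mean squared error in target units (seconds)."""
    p = _pair(pair_or_obs, pred)
    return float(np.sqrt(np.mean((p.pred - p.obs) ** 2)))


def nrmse(pair_or_rmse, obs_min: float | None = None, obs_max: float | None = None,
          pred=None) -> float:
    """Range-normalized RMSE in percent: ``rmse / (obs_max − obs_min) · 100``.

    Accepts either a :class:`PredictionPair` (or obs, pred vectors), from
    which the range is taken, or a precomputed ``(rmse, obs_min, obs_max)``
    triple — the latter lets printed summary errors be re-normalized.
    """
    if obs_min is not None and obs_max is not None and np.isscalar(pair_or_rmse):
        err, lo, hi = float(pair_or_rmse), float(obs_min), float(obs_max)
    else:
        p = _pair(pair_or_rmse, pred)
        err, lo, hi = rmse(p), float(np.min(p.obs)), float(np.max(p.obs))
    if not hi > lo:
        raise DomainError(f"observed range must be positive, got [{lo}, {hi}]")
    return err / (hi - lo) * 100.0


def r2(pair_or_obs, pred=None) -> float:
    """Coefficient of determination ``1 − SS_res/SS_tot``; may be negative."""
    p = _pair(pair_or_obs, pred)
    if p.n < 2:
        raise ContractError("r2 requires at least two observations")
    ss_tot = float(np.sum((p.obs - p.obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("observed values are constant; r2 undefined")
    ss_res = float(np.sum((p.pred - p.obs) ** 2))
    return 1.0 - ss_res / ss_tot


def evaluate(obs, pred) -> EvaluationResult:
    """All three metrics for one observed/predicted pair."""
    p = _pair(obs, pred)
    return EvaluationResult(rmse=rmse(p), nrmse=nrmse(p), r2=r2(p))


@dataclass(frozen=True)
class CVPlan:
    """A k-fold assignment of records, stratified on the target.

    ``assignments`` maps record_id to a fold index in ``1..k``. Folds
    partition the records and differ in size by at most one.
    """

    k: int
    assignments: Mapping[str, int]
    seed: int
    n_bins: int
    balance_report: dict = field(default_factory=dict)

    def fold_of(self, record_id: str) -> int:
        return self.assignments[str(record_id)]

    def fold_indices(self, record_ids: Sequence[str]) -> np.ndarray:
        """Fold index per record, aligned with ``record_ids``."""
        return np.array([self.assignments[str(r)] for r in record_ids], dtype=int)

    def test_masks(self, record_ids: Sequence[str]):
        """Yield ``(fold, boolean test mask)`` pairs in fold order."""
        folds = self.fold_indices(record_ids)
        for f in range(1, self.k + 1):
            yield f, folds == f

    def fold_sizes(self) -> list[int]:
        folds = np.array(list(self.assignments.values()))
        return [int(np.sum(folds == f)) for f in range(1, self.k + 1)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"record_id": list(self.assignments), "fold": list(self.assignments.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1, n_bins: int = 0) -> "CVPlan":
        df = pd.read_csv(path, dtype={"record_id": str, "fold": int})
        assignments = dict(zip(df["record_id"], df["fold"]))
        return cls(k=int(df["fold"].max()), assignments=assignments, seed=seed, n_bins=n_bins)


def balanced_kfold(
    table_or_y,
    k: int = 10,
    seed: int = 0,
    n_bins: int = 10,
    record_ids: Sequence[str] | None = None,
) -> CVPlan:
    """Target-stratified k-fold split with near-equal fold sizes.

    Records are ranked by target value, grouped into ``n_bins`` quantile
    bins, shuffled within each bin with the given seed, and dealt to folds
    cyclically across the bin-ordered sequence. Each fold therefore draws
    records from every part of the target distribution, and fold sizes
    differ by at most one. The returned plan's ``balance_report`` records
    the per-fold target means against the global mean.
    """
    if hasattr(table_or_y, "y"):
        y = np.asarray(table_or_y.y, dtype=float)
        if record_ids is None:
            record_ids = table_or_y.record_ids
    else:
        y = np.asarray(table_or_y, dtype=float)
        if record_ids is None:
            record_ids = [str(i) for i in range(y.size)]
    n = y.size
    if k < 2:
        raise ContractError("k must be at least 2")
    if k > n:
        raise ContractError(f"k={k} exceeds record count n={n}")

    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    n_bins_eff = max(1, min(n_bins, n // k if n // k else 1, n))
    bins = np.array_split(order, n_bins_eff)
    sequence: list[int] = []
    for b in bins:
        b = b.copy()
        rng.shuffle(b)
        sequence.extend(int(i) for i in b)

    folds = np.empty(n, dtype=int)
    start = int(rng.integers(k))  # rotate so no fold is systematically favoured
    for pos, idx in enumerate(sequence):
        folds[idx] = (pos + start) % k + 1

    assignments = {str(record_ids[i]): int(folds[i]) for i in range(n)}
    global_mean = float(y.mean())
    fold_means = {f: float(y[folds == f].mean()) for f in range(1, k + 1)}
    report = {
        "global_mean": global_mean,
        "fold_means": fold_means,
        "max_abs_deviation": max(abs(m - global_mean) for m in fold_means.values()),
    }
    return CVPlan(k=k, assignments=assignments, seed=seed, n_bins=n_bins_eff,
                  balance_report=report)
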