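"""Shapley-value attribution and partial dependence for fitted models.

Attribution treats a prediction as a cooperative game: the "players" are the
model's features, and the value of a coalition ``S`` is the model prediction
with the features in ``S`` taken from the explained instance ``x`` and the
remaining features marginalized — replaced by background data and averaged
(interventional marginalization). The Shapley value of feature ``j``,

    phi_j = sum over S not containing j of
            |S|! (p - |S| - 1)! / p!  *  ( val(S ∪ {j}) - val(S) ),

is the unique attribution satisfying the efficiency, symmetry, dummy and
additivity axioms. ``exact_shapley`` enumerates all 2^p coalitions (feasible
for p up to ~15); ``sampled_shapley`` is a permutation-sampling Monte Carlo
estimator with antithetic pairs and per-feature standard errors, for the
high-dimensional models the pipeline actually produces.

The background distribution is summarized by weighted k-means centroids
(default k = 12) so that each coalition value costs k predictions instead of
one per training record.

Partial dependence marginalizes the model over the empirical distribution of
the complementary features:

    pd_S(g) = mean over records r of  f(x_r with features S overwritten by g),

evaluated on a grid over one or two features; the two-feature case yields the
surfaces used to study, e.g., API lipophilicity against super-disintegrant
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .errors import ContractError, DomainError
from .io import FormulationTable
from .models import TrainedModel

__all__ = [
    "Background",
    "ShapleyExplanation",
    "ShapMatrix",
    "PDPResult",
    "kmeans_background",
    "coalition_value",
    "exact_shapley",
    "sampled_shapley",
    "shap_matrix",
    "partial_dependence",
    "plot_shap_summary",
    "plot_dependence",
    "plot_pdp",
]


@dataclass(frozen=True)
class Background:
    """Representative feature vectors with non-negative weights summing to 1."""

    points: np.ndarray
    weights: np.ndarray
    k: int
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if pts.ndim != 2 or w.ndim != 1 or w.size != pts.shape[0]:
            raise ContractError("background points/weights misaligned")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ContractError("background weights must be non-negative and sum to 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_rows(cls, X, feature_names=None) -> "Background":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        return cls(points=X, weights=np.full(n, 1.0 / n), k=n,
                   feature_names=tuple(feature_names) if feature_names else None)


def kmeans_background(X, k: int = 12, seed: int = 0,
                      feature_names: Sequence[str] | None = None) -> Background:
    """Summarize a feature matrix into ``k`` weighted k-means centroids.

    Clustering is performed in standardized space (so percentage columns and
    descriptor columns contribute comparably); centroids are returned in the
    original units, weighted by cluster occupancy.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ContractError("X must be 2-D")
    if k < 1 or k > X.shape[0]:
        raise ContractError(f"k={k} must be in [1, rows={X.shape[0]}]")
    if k == 1:
        pts = X.mean(axis=0, keepdims=True)
        return Background(points=pts, weights=np.array([1.0]), k=1,
                          feature_names=tuple(feature_names) if feature_names else None)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    counts = np.bincount(km.labels_, minlength=k).astype(float)
    centroids = scaler.inverse_transform(km.cluster_centers_)
    return Background(points=centroids, weights=counts / counts.sum(), k=k,
                      feature_names=tuple(feature_names) if feature_names else None)


# ---------------------------------------------------------------------------
# Coalition values
# ---------------------------------------------------------------------------

def _feature_indices(model: TrainedModel, S: Sequence) -> np.ndarray:
    names = model.feature_names
    idx = []
    for s in S:
        if isinstance(s, (int, np.integer)):
            if not 0 <= int(s) < len(names):
                raise ContractError(f"feature index {s} out of range")
            idx.append(int(s))
        else:
            if s not in names:
                raise ContractError(f"unknown feature {s!r}")
            idx.append(names.index(s))
    return np.array(sorted(set(idx)), dtype=int)


def coalition_value(model: TrainedModel, x, S: Sequence, bg: Background) -> float:
    """Value of coalition ``S``: prediction with features in S pinned to x and
    the rest marginalized over the weighted background."""
    x = np.asarray(x, dtype=float).ravel()
    idx = _feature_indices(model, S)
    Z = bg.points.copy()
    Z[:, idx] = x[idx]
    return float(bg.weights @ model.predict(Z))


def _all_coalition_values(model: TrainedModel, x: np.ndarray, bg: Background,
                          chunk_masks: int = 2048) -> np.ndarray:
    """val(S) for every bitmask S in 0..2^p−1, batched for predict efficiency."""
    p = x.size
    n_bg = bg.points.shape[0]
    n_masks = 1 << p
    bits = ((np.arange(n_masks)[:, None] >> np.arange(p)[None, :]) & 1).astype(bool)
    vals = np.empty(n_masks)
    for lo in range(0, n_masks, chunk_masks):
        hi = min(lo + chunk_masks, n_masks)
        m = bits[lo:hi]  # (chunk, p)
        Z = np.where(m[:, None, :], x[None, None, :], bg.points[None, :, :])
        preds = model.predict(Z.reshape(-1, p)).reshape(hi - lo, n_bg)
        vals[lo:hi] = preds @ bg.weights
    return vals


@dataclass
class ShapleyExplanation:
    """Per-feature attributions phi (target units, s) for one instance."""

    phi: dict[str, float]
    base_value: float
    x: dict[str, float]
    estimator: str
    n_samples: int | None = None
    mc_stderr: dict[str, float] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def prediction(self) -> float:
        return self.base_value + sum(self.phi.values())

    def phi_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else list(self.phi)
        return np.array([self.phi[c] for c in order])


def exact_shapley(model: TrainedModel, x, bg: Background,
                  p_limit: int = 15) -> ShapleyExplanation:
    """Exact Shapley attribution by full coalition enumeration.

    Cost is 2^p coalition evaluations; above ``p_limit`` features the caller
    is directed to :func:`sampled_shapley`.
    """
    x = np.asarray(x, dtype=float).ravel()
    p = x.size
    if p != len(model.feature_names):
        raise ContractError("x length does not match model features")
    if p > p_limit:
        raise ContractError(
            f"p={p} exceeds p_limit={p_limit}; use sampled_shapley for high dimensions"
        )
    vals = _all_coalition_values(model, x, bg)
    sizes = np.array([bin(m).count("1") for m in range(1 << p)])
    # subset weights |S|!(p−|S|−1)!/p! indexed by |S|
    w = np.array([factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)])
    phi = np.zeros(p)
    masks = np.arange(1 << p)
    for j in range(p):
        without_j = masks[(masks >> j) & 1 == 0]
        s = sizes[without_j]
        phi[j] = np.sum(w[s] * (vals[without_j | (1 << j)] - vals[without_j]))
    base = float(vals[0])
    fx = float(vals[-1])
    residual = fx - base - float(phi.sum())
    names = model.feature_names
    return ShapleyExplanation(
        phi={c: float(v) for c, v in zip(names, phi)},
        base_value=base,
        x={c: float(v) for c, v in zip(names, x)},
        estimator="exact",
        metadata={"prediction": fx, "efficiency_residual": residual},
    )


def sampled_shapley(model: TrainedModel, x, bg: Background,
                    n_samples: int = 2000, seed: int = 0) -> ShapleyExplanation:
    """Permutation-sampling Shapley estimator with antithetic pairs.

    ``n_samples`` permutations are drawn in antithetic pairs (a permutation
    and its reverse); each contributes one marginal-contribution sample per
    feature. Per-feature Monte-Carlo standard errors are computed over the
    paired samples. The tiny efficiency residual left by floating-point
    accumulation is redistributed proportionally to |phi| and recorded.
    """
    if n_samples < 10:
        raise ContractError("n_samples must be >= 10")
    x = np.asarray(x, dtype=float).ravel()
    p = x.size
    if p != len(model.feature_names):
        raise ContractError("x length does not match model features")
    rng = np.random.default_rng(seed)
    n_pairs = max(1, n_samples // 2)
    n_bg = bg.points.shape[0]

    pair_samples = np.empty((n_pairs, p))

    def contributions(perm: np.ndarray) -> np.ndarray:
        # cumulative prefix masks: row t pins perm[:t] to x
        mask = np.zeros((p + 1, p), dtype=bool)
        mask[1:, :] = np.cumsum(np.eye(p, dtype=bool)[perm], axis=0)
        Z = np.where(mask[:, None, :], x[None, None, :], bg.points[None, :, :])
        preds = model.predict(Z.reshape(-1, p)).reshape(p + 1, n_bg)
        vals = preds @ bg.weights
        contrib = np.empty(p)
        contrib[perm] = np.diff(vals)
        return contrib

    for i in range(n_pairs):
        perm = rng.permutation(p)
        c1 = contributions(perm)
        c2 = contributions(perm[::-1])
        pair_samples[i] = 0.5 * (c1 + c2)

    phi = pair_samples.mean(axis=0)
    if n_pairs > 1:
        stderr = pair_samples.std(axis=0, ddof=1) / np.sqrt(n_pairs)
    else:
        stderr = np.full(p, np.inf)

    base = coalition_value(model, x, [], bg)
    fx = coalition_value(model, x, list(range(p)), bg)
    residual = fx - base - float(phi.sum())
    abs_phi = np.abs(phi)
    if abs_phi.sum() > 0:
        phi = phi + residual * abs_phi / abs_phi.sum()
    names = model.feature_names
    return ShapleyExplanation(
        phi={c: float(v) for c, v in zip(names, phi)},
        base_value=float(base),
        x={c: float(v) for c, v in zip(names, x)},
        estimator="sampled",
        n_samples=2 * n_pairs,
        mc_stderr={c: float(s) for c, s in zip(names, stderr)},
        metadata={"prediction": float(fx), "efficiency_residual": float(residual),
                  "residual_redistributed": True, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Matrix of explanations & partial dependence
# ---------------------------------------------------------------------------

@dataclass
class ShapMatrix:
    """Row-wise Shapley explanations for a whole table."""

    phi: pd.DataFrame  # records × features, target units (s)
    base_value: float
    feature_values: pd.DataFrame
    estimator: str

    def ranking(self) -> list[tuple[str, float]]:
        """Features sorted by mean |phi| descending (summary-plot order)."""
        mean_abs = self.phi.abs().mean(axis=0)
        return [(c, float(v)) for c, v in mean_abs.sort_values(ascending=False).items()]

    def dependence_data(self, feature: str) -> pd.DataFrame:
        """(feature value, phi) pairs for a dependence plot."""
        return pd.DataFrame({
            "value": self.feature_values[feature].to_numpy(),
            "phi": self.phi[feature].to_numpy(),
        })

    def to_csv(self, path: str | Path) -> None:
        self.phi.to_csv(path, index=False)


def shap_matrix(model: TrainedModel, table: FormulationTable, bg: Background,
                estimator: str = "auto", n_samples: int = 2000, seed: int = 0,
                p_limit: int = 15,
                feature_columns: Sequence[str] | None = None) -> ShapMatrix:
    """Explain every record of ``table``; rows are instances, columns features."""
    cols = list(feature_columns) if feature_columns is not None else list(model.feature_names)
    if cols != list(model.feature_names):
        raise ContractError("table feature columns must match model features")
    X = table.data[cols].to_numpy(dtype=float)
    p = X.shape[1]
    if estimator == "auto":
        estimator = "exact" if p <= p_limit else "sampled"
    rows = []
    base = None
    for i in range(X.shape[0]):
        if estimator == "exact":
            expl = exact_shapley(model, X[i], bg, p_limit=p_limit)
        else:
            expl = sampled_shapley(model, X[i], bg, n_samples=n_samples,
                                   seed=int((seed + 7919 * i) % (2**31 - 1)))
        rows.append([expl.phi[c] for c in cols])
        base = expl.base_value
    return ShapMatrix(
        phi=pd.DataFrame(rows, columns=cols),
        base_value=float(base),
        feature_values=pd.DataFrame(X, columns=cols),
        estimator=estimator,
    )


@dataclass
class PDPResult:
    """Partial-dependence values over a 1- or 2-feature grid."""

    features: tuple[str, ...]
    grid: tuple[np.ndarray, ...]
    values: np.ndarray  # (g1,) or (g1, g2)
    n_background: int

    def to_frame(self) -> pd.DataFrame:
        if len(self.features) == 1:
            return pd.DataFrame({self.features[0]: self.grid[0], "pd": self.values})
        g1, g2 = np.meshgrid(self.grid[0], self.grid[1], indexing="ij")
        return pd.DataFrame({
            self.features[0]: g1.ravel(),
            self.features[1]: g2.ravel(),
            "pd": self.values.ravel(),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _make_grid(v: np.ndarray, spec) -> np.ndarray:
    if isinstance(spec, (list, tuple, np.ndarray)):
        return np.asarray(spec, dtype=float)
    n = int(spec)
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        return np.array([lo])
    return np.linspace(lo, hi, n)


def partial_dependence(model: TrainedModel, table_or_X, S: Sequence[str],
                       grid: int | Sequence = 20,
                       percentiles: tuple[float, float] | None = None) -> PDPResult:
    """Empirical partial dependence of the model on 1 or 2 features.

    For each grid point the features in ``S`` are overwritten in *every*
    record and the predictions averaged — marginalization over the empirical
    distribution of the remaining features. ``grid`` is a point count per
    feature (default 20, equally spaced between observed min and max, or
    between the given ``percentiles`` of the observed values) or explicit
    per-feature value sequences.
    """
    S = list(S)
    if not 1 <= len(S) <= 2:
        raise ContractError("partial dependence supports 1 or 2 features")
    if isinstance(table_or_X, FormulationTable):
        X = table_or_X.data[list(model.feature_names)].to_numpy(dtype=float)
    elif isinstance(table_or_X, pd.DataFrame):
        X = table_or_X[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(table_or_X, dtype=float)
    idx = [_feature_indices(model, [s])[0] for s in S]

    grids = []
    grid_specs = grid if isinstance(grid, (list, tuple)) and len(S) == 2 and not np.isscalar(grid[0]) else None
    for a, j in enumerate(idx):
        col = X[:, j]
        if percentiles is not None:
            lo, hi = np.percentile(col, [percentiles[0], percentiles[1]])
            col = np.clip(col, lo, hi)
        spec_a = grid_specs[a] if grid_specs is not None else grid
        grids.append(_make_grid(col, spec_a))

    if len(S) == 1:
        g = grids[0]
        Z = np.repeat(X[None, :, :], len(g), axis=0)
        Z[:, :, idx[0]] = g[:, None]
        preds = model.predict(Z.reshape(-1, X.shape[1])).reshape(len(g), X.shape[0])
        values = preds.mean(axis=1)
    else:
        g1, g2 = grids
        values = np.empty((len(g1), len(g2)))
        for a, v1 in enumerate(g1):
            Z = np.repeat(X[None, :, :], len(g2), axis=0)
            Z[:, :, idx[0]] = v1
            Z[:, :, idx[1]] = g2[:, None]
            preds = model.predict(Z.reshape(-1, X.shape[1])).reshape(len(g2), X.shape[0])
            values[a] = preds.mean(axis=1)
    names = tuple(model.feature_names[j] for j in idx)
    return PDPResult(features=names, grid=tuple(grids), values=values,
                     n_background=X.shape[0])


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def _save(fig, path):
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        import matplotlib.pyplot as plt
        plt.close(fig)
    return fig


def plot_shap_summary(matrix: ShapMatrix, top: int = 20, path=None):
    """Summary plot: per-feature attribution spread, colored by feature value."""
    import matplotlib.pyplot as plt

    ranking = matrix.ranking()[:top]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(ranking) + 1.5))
    rng = np.random.default_rng(0)
    for row, (feat, _) in enumerate(reversed(ranking)):
        phi = matrix.phi[feat].to_numpy()
        vals = matrix.feature_values[feat].to_numpy()
        rng_v = np.ptp(vals)
        color = (vals - vals.min()) / rng_v if rng_v > 0 else np.full_like(vals, 0.5)
        jitter = rng.normal(0, 0.08, len(phi))
        ax.scatter(phi, row + jitter, c=color, cmap="coolwarm", s=12, alpha=0.8)
    ax.set_yticks(range(len(ranking)))
    ax.set_yticklabels([f for f, _ in reversed(ranking)], fontsize=8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Shapley value [s] (impact on predicted disintegration time)")
    return _save(fig, path)


def plot_dependence(matrix: ShapMatrix, feature: str, path=None):
    """Dependence plot: feature value against its attribution per record."""
    import matplotlib.pyplot as plt

    data = matrix.dependence_data(feature)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(data["value"], data["phi"], s=14, alpha=0.8)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(feature)
    ax.set_ylabel("Shapley value [s]")
    return _save(fig, path)


def plot_pdp(result: PDPResult, path=None):
    """Line (1 feature) or filled-surface (2 features) partial-dependence plot."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    if len(result.features) == 1:
        ax.plot(result.grid[0], result.values)
        ax.set_xlabel(result.features[0])
        ax.set_ylabel("Mean predicted disintegration time [s]")
    else:
        mesh = ax.pcolormesh(result.grid[0], result.grid[1], result.values.T,
                             shading="auto", cmap="viridis")
        fig.colorbar(mesh, ax=ax, label="Mean predicted disintegration time [s]")
        ax.set_xlabel(result.features[0])
        ax.set_ylabel(result.features[1])
    return _save(fig, path)
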