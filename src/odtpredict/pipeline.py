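"""End-to-end workflow orchestration: preprocess → select → train → explain.

One :class:`PipelineConfig` drives the whole run; a single global seed fans
out deterministically to per-stage seeds (numpy ``SeedSequence`` with the
stage index as spawn key), and every seed actually consumed is logged and
recorded in the :class:`RunReport`, which together with the input files fully
determines a re-run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptors import add_geometry_columns, drop_degenerate_columns, merge_api_descriptors, read_descriptor_table
from .errors import ContractError, OdtError
from .explain import kmeans_background, partial_dependence, plot_dependence, plot_pdp, plot_shap_summary, shap_matrix, sampled_shapley, exact_shapley
from .io import FormulationTable, filter_by_disintegration, read_formulation_table, split_silica_variable, validate_table, write_formulation_table
from .model import DisintegrationModel
from .models import SearchBudget, load_model
from .selection import SelectedFeatures
from .synthetic import GeneratorConfig, generate_dataset

log = logging.getLogger("odtpredict")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "predict_with_bundle"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults mirror the reference workflow
    settings (25 five-fold selection loops at threshold 0.1, a 10-fold final
    model, a 12-centroid explanation background)."""

    formulation_csv: str | None = None
    descriptor_csv: str | None = None
    output_dir: str = "odt_run"
    # preprocessing
    filter_max_time: float = 180.0
    apply_silica_split: bool = True
    validation_tolerance: float = 2.0
    # synthetic input (used when formulation_csv is None)
    synthetic_n: int = 250
    # feature selection
    selection_n_loops: int = 25
    selection_k: int = 5
    selection_threshold: float = 0.1
    selection_n_starts: int = 1
    selection_families: tuple[str, ...] = ("gradient_boosting",)
    # final model
    final_k: int = 10
    final_n_starts: int = 30
    families: tuple[str, ...] = ("gradient_boosting", "random_forest", "penalized_linear")
    include_stacked: bool = False
    max_iterations: int | None = None
    max_time_s: float | None = None
    # explanation
    kmeans_k: int = 12
    shap_estimator: str = "auto"
    shap_n_samples: int = 500
    shap_max_records: int | None = 50
    pdp_grid: int = 20
    # global
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        for key in ("selection_families", "families"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
                   .generate_state(1)[0] % (2**31 - 1))

    def budget(self) -> SearchBudget:
        return SearchBudget(max_iterations=self.max_iterations, max_time_s=self.max_time_s)


@dataclass
class RunReport:
    """Provenance and artifact index for one pipeline run."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, **info) -> None:
        self.stages[stage] = {"seconds": round(seconds, 3), **info}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _load_inputs(cfg: PipelineConfig, out: Path, report: RunReport) -> FormulationTable:
    seed = cfg.stage_seed(0)
    report.seeds["input"] = seed
    if cfg.formulation_csv is None:
        gen = GeneratorConfig(n=cfg.synthetic_n, seed=seed)
        table, truth, desc = generate_dataset(gen)
        write_formulation_table(table, out / "synthetic_formulations.csv")
        truth.to_json(out / "ground_truth.json")
        report.artifacts["synthetic_formulations"] = str(out / "synthetic_formulations.csv")
        log.info("generated %d synthetic formulations (seed %d)", table.n, seed)
        return table
    table = read_formulation_table(cfg.formulation_csv)
    if cfg.apply_silica_split:
        table, warnings = split_silica_variable(table)
        for w in warnings:
            log.warning("silica split: %s", w)
    if cfg.descriptor_csv:
        desc = read_descriptor_table(cfg.descriptor_csv)
        table = add_geometry_columns(table)
        table = merge_api_descriptors(table, desc)
    return table


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute read → filter → enrich → select → final model → explanation.

    Any stage failure raises with a stage-tagged message; artifacts written
    by earlier stages are retained in the output directory.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(cfg))
    stage = "input"
    try:
        t0 = time.perf_counter()
        table = _load_inputs(cfg, out, report)
        report.record(stage, time.perf_counter() - t0, n_records=table.n)

        stage = "preprocess"
        t0 = time.perf_counter()
        n_before = table.n
        table = filter_by_disintegration(table, cfg.filter_max_time)
        validation = validate_table(table, tolerance=cfg.validation_tolerance)
        validation.to_json(out / "validation_report.json")
        table, dropped = drop_degenerate_columns(table)
        report.record(stage, time.perf_counter() - t0, n_before=n_before,
                      n_after=table.n, n_excluded=n_before - table.n,
                      dropped_columns=dropped, n_validation_findings=len(validation.findings))
        report.artifacts["validation_report"] = str(out / "validation_report.json")
        log.info("preprocess: %d -> %d records (%d excluded > %g s)", n_before,
                 table.n, n_before - table.n, cfg.filter_max_time)

        stage = "select"
        t0 = time.perf_counter()
        seed = cfg.stage_seed(1)
        report.seeds["selection"] = seed
        model = DisintegrationModel(table, families=cfg.families)
        selected = model.select_features(
            n_loops=cfg.selection_n_loops, k=cfg.selection_k,
            threshold=cfg.selection_threshold, seed=seed, budget=cfg.budget(),
            n_starts=cfg.selection_n_starts, families=cfg.selection_families)
        selected.to_json(out / "selected_features.json")
        model.importance.to_csv(out / "variable_importance.csv")
        report.record(stage, time.perf_counter() - t0, n_selected=len(selected.names))
        report.artifacts["selected_features"] = str(out / "selected_features.json")
        report.artifacts["variable_importance"] = str(out / "variable_importance.csv")
        log.info("selected %d / %d features (threshold %g, seed %d)",
                 len(selected.names), len(table.feature_columns),
                 cfg.selection_threshold, seed)

        stage = "train"
        t0 = time.perf_counter()
        seed = cfg.stage_seed(2)
        report.seeds["train"] = seed
        results = model.fit(k=cfg.final_k, n_starts=cfg.final_n_starts, seed=seed,
                            budget=cfg.budget(), include_stacked=cfg.include_stacked)
        bundle = out / "model_bundle"
        results.save(bundle)
        (out / "metrics.json").write_text(json.dumps({
            "pooled": results.pooled.as_dict(),
            "per_fold": [r.as_dict() for r in results.cv.per_fold],
            "multistart": results.leaderboard.summary(),
            "best_spec": results.best_spec.as_dict(),
        }, indent=2), encoding="utf-8")
        (out / "summary.txt").write_text(results.summary() + "\n", encoding="utf-8")
        report.record(stage, time.perf_counter() - t0,
                      best_family=results.best_spec.family,
                      pooled=results.pooled.as_dict())
        report.artifacts["model_bundle"] = str(bundle)
        report.artifacts["metrics"] = str(out / "metrics.json")
        log.info("final model: %s, pooled RMSE %.3f s, NRMSE %.2f %%, R2 %.3f",
                 results.best_spec.family, results.rmse, results.nrmse, results.r2)

        stage = "explain"
        t0 = time.perf_counter()
        seed = cfg.stage_seed(3)
        report.seeds["explain"] = seed
        matrix = results.shap_values(estimator=cfg.shap_estimator,
                                     n_samples=cfg.shap_n_samples, seed=seed,
                                     k_background=cfg.kmeans_k,
                                     max_records=cfg.shap_max_records)
        matrix.to_csv(out / "shap_matrix.csv")
        ranking = matrix.ranking()
        (out / "shap_ranking.json").write_text(
            json.dumps([{"feature": f, "mean_abs_phi": v} for f, v in ranking], indent=2),
            encoding="utf-8")
        plot_shap_summary(matrix, path=out / "shap_summary.svg")
        top = ranking[0][0]
        plot_dependence(matrix, top, path=out / "shap_dependence_top.svg")
        pdp1 = results.partial_dependence([top], grid=cfg.pdp_grid)
        pdp1.to_csv(out / "pdp_top_feature.csv")
        plot_pdp(pdp1, path=out / "pdp_top_feature.svg")
        pdp2 = None
        names = results.final_model.feature_names
        if len(names) >= 2 and len(ranking) >= 2:
            pair = (ranking[0][0], ranking[1][0])
            pdp2 = results.partial_dependence(list(pair), grid=min(cfg.pdp_grid, 12))
            pdp2.to_csv(out / "pdp_surface.csv")
            plot_pdp(pdp2, path=out / "pdp_surface.svg")
        report.record(stage, time.perf_counter() - t0,
                      n_explained=matrix.phi.shape[0], estimator=matrix.estimator,
                      top_feature=top)
        for name in ("shap_matrix.csv", "shap_ranking.json", "shap_summary.svg",
                     "pdp_top_feature.csv"):
            report.artifacts[name.split(".")[0]] = str(out / name)

        report.to_json(out / "run_report.json")
        report.artifacts["run_report"] = str(out / "run_report.json")
        return report
    except OdtError as err:
        report.record(stage, 0.0, error=str(err))
        report.to_json(out / "run_report.json")
        raise OdtError(f"[stage: {stage}] {err}") from err


def predict_with_bundle(bundle_dir: str | Path, rows: pd.DataFrame,
                        explain: bool = False, n_samples: int = 500,
                        seed: int = 0) -> pd.DataFrame:
    """Predict disintegration times for new formulations from a saved bundle.

    ``rows`` must contain the bundle's feature columns (after any geometry /
    descriptor enrichment). With ``explain=True``, a per-prediction Shapley
    attribution against a background built from the provided rows is added
    (efficiency holds: the attributions sum to prediction − base).
    """
    model = load_model(bundle_dir)
    missing = [c for c in model.feature_names if c not in rows.columns]
    if missing:
        raise ContractError(f"missing feature column(s): {missing}")
    preds = model.predict(rows)
    result = rows.copy()
    result["Predicted disintegration time [s]"] = preds
    if explain:
        X = rows[model.feature_names].to_numpy(dtype=float)
        k = min(12, X.shape[0])
        bg = kmeans_background(X, k=k, seed=seed, feature_names=model.feature_names)
        p = len(model.feature_names)
        for i in range(X.shape[0]):
            expl = (exact_shapley(model, X[i], bg) if p <= 12 else
                    sampled_shapley(model, X[i], bg, n_samples=n_samples,
                                    seed=int((seed + i) % (2**31 - 1))))
            for c, v in expl.phi.items():
                result.loc[result.index[i], f"phi({c})"] = v
            result.loc[result.index[i], "base_value"] = expl.base_value
    return result
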