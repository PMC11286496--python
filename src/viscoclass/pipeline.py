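"""End-to-end experiment orchestration and reproducible presets.

``run_pipeline`` executes simulate -> extract -> classify -> select ->
assess for one configuration and writes all artifacts (feature table,
metrics, ablation and recovery reports, run manifest) to an output
directory.  ``headline_metrics`` computes the standard battery of
classification figures for one cohort seed and is the single entry point
used by both the acceptance script and the test suite.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assessment import recovery_report
from .classify import (
    DEFAULT_C_GRID,
    DEFAULT_SIGMA_GRID,
    cross_validate,
    evaluate,
    pearson_matrix,
    split_train_test,
    train_classifier,
)
from .cohort import (
    CohortConfig,
    CohortDataset,
    default_group_specs,
    generate_cohort,
    write_cohort,
)
from .extraction import MARKERS, extract_features
from .rheology import IndentationProtocol
from .selection import ablation_report, rfe_rank

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "headline_metrics",
    "task_accuracy",
    "single_marker_rocs",
]

log = logging.getLogger("viscoclass")

#: experiment task definitions: subsets of statuses
TASKS = {
    "HD": (0, 2),
    "HT": (0, 1),
    "TD": (1, 2),
    "HTD": (0, 1, 2),
}


@dataclass
class PipelineConfig:
    n_per_group: int = 800
    noise_sd: float = 0.03
    seed: int = 1
    r2_min: float = 0.9
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    cv_folds: int = 10
    tune: bool = True
    output_dir: str = "results"
    write_measurements: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("c_grid", "sigma_grid"):
            if key in raw:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def build_cohort(config: PipelineConfig) -> CohortDataset:
    specs = tuple(
        s.__class__(**{**s.__dict__, "n": config.n_per_group})
        for s in default_group_specs()
    )
    return generate_cohort(
        CohortConfig(
            group_specs=specs,
            protocol=IndentationProtocol(),
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
    )


def task_accuracy(
    table: pd.DataFrame,
    statuses: tuple[int, ...],
    features: list[str],
    seed: int,
    tune: bool = True,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    cv_folds: int = 10,
) -> float:
    """Held-out accuracy for one classification task.

    Stratified 70/30 split; (C, sigma) tuned by stratified k-fold grid
    search on the training split only.
    """
    sub = table[table["status"].isin(statuses)]
    train, test = split_train_test(sub, seed=seed)
    if tune:
        C, sigma, _, _ = cross_validate(
            train, features, k=cv_folds, c_grid=c_grid, sigma_grid=sigma_grid, seed=seed
        )
    else:
        C, sigma = 10.0, 2.0
    clf = train_classifier(train, features, C=C, sigma=sigma)
    return evaluate(clf, test).accuracy


def headline_metrics(
    seed: int,
    n_per_group: int = 800,
    tune: bool = True,
    table: pd.DataFrame | None = None,
    with_truth: bool = True,
) -> dict:
    """The standard battery of figures for one cohort seed.

    Simulates the three-group cohort, extracts the nine markers and
    reports: pairwise and three-state accuracies with all nine markers,
    single-marker accuracies (Esum, fT, alphaR), the top-5 three-state
    accuracy with SVM-RFE ranking, the median fit R-squared, and the
    ground-truth group means of Esum.
    """
    cfg = PipelineConfig(seed=seed, n_per_group=n_per_group, tune=tune)
    out: dict = {"seed": seed}
    if table is None:
        dataset = build_cohort(cfg)
        table, report = extract_features(dataset, r2_min=cfg.r2_min, seed=seed)
        out["median_r2"] = report.median_r2
        out["n_kept"] = report.n_kept
        if with_truth:
            truth = dataset.ground_truth
            means = truth.groupby("status")["Esum"].mean()
            out["esum_mean_healthy"] = float(means.loc[0])
            out["esum_mean_treated"] = float(means.loc[1])
            out["esum_mean_diseased"] = float(means.loc[2])

    out["acc_hd_all9"] = task_accuracy(table, TASKS["HD"], MARKERS, seed, tune)
    out["acc_ht_all9"] = task_accuracy(table, TASKS["HT"], MARKERS, seed, tune)
    out["acc_td_all9"] = task_accuracy(table, TASKS["TD"], MARKERS, seed, tune)
    out["acc_hd_esum"] = task_accuracy(table, TASKS["HD"], ["Esum"], seed, tune)
    out["acc_hd_ft"] = task_accuracy(table, TASKS["HD"], ["fT"], seed, tune)
    out["acc_3c_esum"] = task_accuracy(table, TASKS["HTD"], ["Esum"], seed, tune)
    out["acc_3c_alphar"] = task_accuracy(table, TASKS["HTD"], ["alphaR"], seed, tune)

    train, _ = split_train_test(table, seed=seed)
    ranking, _ = rfe_rank(train, MARKERS)
    out["rfe_ranking"] = ranking
    out["acc_3c_top5"] = task_accuracy(table, TASKS["HTD"], ranking[:5], seed, tune)
    return out


def single_marker_rocs(
    table: pd.DataFrame,
    out_dir: str | Path,
    statuses: tuple[int, ...] = TASKS["HD"],
    seed: int = 1,
) -> list[Path]:
    """One ROC CSV per marker for a binary task (default healthy/diseased)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub = table[table["status"].isin(statuses)]
    train, test = split_train_test(sub, seed=seed)
    paths = []
    for marker in MARKERS:
        clf = train_classifier(train, [marker], C=10.0, sigma=2.0)
        metrics = evaluate(clf, test)
        points = next(iter(metrics.roc_points.values()))
        path = out / f"roc_{marker}.csv"
        pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(path, index=False)
        paths.append(path)
    return paths


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and write the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        dataset = build_cohort(config)
        if config.write_measurements:
            write_cohort(dataset, out / "cohort")
        dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False)

        stage = "extract"
        table, report = extract_features(dataset, r2_min=config.r2_min, seed=config.seed)
        table.to_csv(out / "feature_table.csv", index=False)
        (out / "fit_report.json").write_text(json.dumps(report.as_dict(), indent=2))

        stage = "classify"
        metrics = headline_metrics(config.seed, tune=config.tune, table=table)
        pearson_matrix(table.drop(columns=["measurement_id"])).to_csv(out / "pearson.csv")

        stage = "select"
        report = ablation_report(table, k_folds=config.cv_folds, seed=config.seed)
        ablation = {
            "ranking": report.ranking,
            "normalized_importance": report.normalized_importance,
            "optimal_k": report.optimal_k,
            "accuracy_vs_k": list(map(float, report.accuracy_vs_k)),
            "curve_high_to_low": list(map(float, report.curve_high_to_low)),
            "curve_low_to_high": list(map(float, report.curve_low_to_high)),
        }
        (out / "ablation_report.json").write_text(json.dumps(ablation, indent=2))

        stage = "assess"
        recovery = recovery_report(table, seed=config.seed, tune=config.tune)
        (out / "recovery_report.json").write_text(json.dumps(recovery.as_dict(), indent=2))

        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=str))
        manifest = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": _versions(),
            "artifacts": sorted(p.name for p in out.iterdir()),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        log.exception("pipeline stage %r failed", stage)
        raise
    return out


def _versions() -> dict:
    import sklearn
    import scipy

    from . import __version__

    return {
        "viscoclass": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pandas": pd.__version__,
    }
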