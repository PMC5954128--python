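"""End-to-end drug-likeness data-mining run from one declarative config.

Two stages: (1) visualization — information-gain screen, t-SNE and PCA
maps of the normalized feature space with their trust scores; (2)
classification — representative train/test split, six base classifiers
plus the AL Boost ensemble trained with stratified cross-validation, and
a metrics table (specificity, sensitivity, CCR, accuracy, variance, MCC
for training and test) per model. Every random stage is seeded from the
config, so a run is a pure function of (input table, config).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    FeatureTable,
    apply_normalizer,
    fit_normalizer,
    read_feature_table,
    write_feature_table,
)
from .embedding import pca_embed, trust, tsne_embed
from .ensemble import fit_alboost, weighted_vote_labels, alboost_predict
from .fixtures import FixtureSpec, make_two_class_table
from .learners import METHOD_LABELS, METHODS, LearnerSpec, predict, train_learner
from .metrics import MetricsReport, compute_report, confusion
from .preprocess import information_gain
from .splitting import AnnealSchedule, stratified_split

__all__ = ["RunConfig", "StageError", "run_workflow", "compare_reports",
           "METRIC_COLUMNS"]

METRIC_COLUMNS = ["specificity", "sensitivity", "ccr", "accuracy", "variance", "mcc"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one workflow run. ``input`` = None draws the synthetic fixture."""

    input: str | None = None
    label_column: str = "label"
    positive_class: str = "drug"
    outdir: str = "alboost_run"
    seed: int = 0

    # synthetic fixture (used when input is None)
    fixture: dict[str, Any] = field(default_factory=dict)

    # visualization stage
    run_embedding: bool = True
    embed_dims: int = 3
    perplexity: float = 30.0
    iterations: int = 1000
    trust_k: int = 10

    # preprocessing
    info_gain_bins: int = 10
    normalization_scope: str = "train"   # "train" (fit on train only) or "all"

    # split stage
    test_fraction: float = 0.2
    split_strategy: str = "sa"
    anneal: dict[str, Any] = field(default_factory=dict)

    # classification stage
    learners: list[str] = field(default_factory=lambda: list(METHODS))
    learner_params: dict[str, dict[str, Any]] = field(default_factory=dict)
    include_alboost: bool = True
    folds: int = 10
    training_metrics: str = "cv"         # "cv" (pooled out-of-fold) or "resub"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.normalization_scope not in ("train", "all"):
            raise ValueError("normalization_scope must be 'train' or 'all'")
        if self.training_metrics not in ("cv", "resub"):
            raise ValueError("training_metrics must be 'cv' or 'resub'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _report_row(report: MetricsReport) -> dict[str, float]:
    return {
        "specificity": report.specificity,
        "sensitivity": report.sensitivity,
        "ccr": report.ccr,
        "accuracy": report.accuracy,
        "variance": report.variance,
        "mcc": report.mcc,
    }


def _load_table(config: RunConfig) -> FeatureTable:
    if config.input is not None:
        return read_feature_table(
            config.input, config.label_column, config.positive_class
        )
    fixture = dict(config.fixture)
    fixture.setdefault("seed", config.seed)
    spec = FixtureSpec(**fixture)
    return make_two_class_table(spec)


def run_workflow(config: RunConfig) -> dict[str, Any]:
    """Execute the full two-stage workflow; returns the artifact dict.

    Writes into ``config.outdir``: the input table (``table.csv``),
    ``info_gain.csv``, embedding coordinates with trust scores,
    train/test id lists, ``metrics.csv`` (one row per model, training and
    test column blocks) and a machine-readable ``run_log.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": [],
    }
    artifacts: dict[str, Any] = {"outdir": outdir, "log": log}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            log["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
            (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
            raise StageError(name, exc) from exc
        log["stages"].append(
            {"stage": name, "status": "ok",
             "elapsed_s": round(time.perf_counter() - t0, 3)}
        )
        return result

    table: FeatureTable = stage("load", lambda: _load_table(config))
    stage("write_table", lambda: write_feature_table(
        table, outdir / "table.csv", config.label_column))
    artifacts["table"] = table

    def _info_gain():
        report = information_gain(table, config.info_gain_bins)
        pd.DataFrame(report.as_pairs(), columns=["feature", "gain_bits"]).to_csv(
            outdir / "info_gain.csv", index=False
        )
        return report

    artifacts["info_gain"] = stage("info_gain", _info_gain)

    whole_norm = apply_normalizer(table, fit_normalizer(table))
    if config.run_embedding:

        def _embed():
            tsne = tsne_embed(
                whole_norm,
                dims=config.embed_dims,
                perplexity=config.perplexity,
                iterations=config.iterations,
                seed=config.seed,
            )
            pca = pca_embed(whole_norm, dims=config.embed_dims)
            scores = {}
            for name, emb in (("tsne", tsne), ("pca", pca)):
                scores[name] = trust(whole_norm, emb, k=config.trust_k).trust
                cols = ["x", "y", "z"][: config.embed_dims]
                frame = pd.DataFrame(emb.coordinates, columns=cols)
                frame.insert(0, "compound_id", table.compound_ids)
                frame.to_csv(outdir / f"{name}_coords.csv", index=False)
            log["trust"] = scores
            return {"tsne": tsne, "pca": pca, "trust": scores}

        artifacts["embedding"] = stage("embedding", _embed)

    def _split():
        schedule = AnnealSchedule(**config.anneal) if config.anneal else None
        result = stratified_split(
            table,
            test_fraction=config.test_fraction,
            seed=config.seed,
            schedule=schedule,
            strategy=config.split_strategy,
        )
        for name, idx in (("train", result.train_indices), ("test", result.test_indices)):
            pd.Series(
                [table.compound_ids[i] for i in idx], name="compound_id"
            ).to_csv(outdir / f"split_{name}.csv", index=False)
        log["split"] = {
            "test_counts": result.test_counts,
            "representativeness_score": result.score,
        }
        return result

    split = stage("split", _split)
    artifacts["split"] = split

    def _classify():
        train_tbl = table.select(split.train_indices)
        test_tbl = table.select(split.test_indices)
        if config.normalization_scope == "train":
            stats = fit_normalizer(train_tbl)
        else:
            stats = fit_normalizer(table)
        train_n = apply_normalizer(train_tbl, stats)
        test_n = apply_normalizer(test_tbl, stats)

        specs = [
            LearnerSpec(m, dict(config.learner_params.get(m, {})), seed=config.seed)
            for m in config.learners
        ]
        ensemble = fit_alboost(specs, train_n, folds=config.folds, seed=config.seed)
        positive = table.class_names[0]
        classes = table.class_names

        rows = {}
        for spec_, cv, model in zip(specs, ensemble.cv_results, ensemble.learners):
            name = METHOD_LABELS[spec_.method]
            if config.training_metrics == "cv":
                train_counts = cv.pooled
            else:
                train_counts = confusion(
                    train_n.labels, predict(model, train_n), positive, classes
                )
            test_counts = confusion(
                test_n.labels, predict(model, test_n), positive, classes
            )
            rows[name] = (compute_report(train_counts), compute_report(test_counts))

        if config.include_alboost:
            if config.training_metrics == "cv":
                oof = np.stack([cv.oof_predictions for cv in ensemble.cv_results])
                train_pred = weighted_vote_labels(oof, ensemble.weights, classes)
            else:
                train_pred = alboost_predict(ensemble, train_n)
            train_counts = confusion(train_n.labels, train_pred, positive, classes)
            test_counts = confusion(
                test_n.labels, alboost_predict(ensemble, test_n), positive, classes
            )
            rows["AL Boost"] = (
                compute_report(train_counts), compute_report(test_counts)
            )

        records = []
        for name, (train_rep, test_rep) in rows.items():
            record = {"model": name}
            record.update({f"train_{k}": v for k, v in _report_row(train_rep).items()})
            record.update({f"test_{k}": v for k, v in _report_row(test_rep).items()})
            records.append(record)
        metrics = pd.DataFrame.from_records(records).set_index("model")
        metrics.round(4).to_csv(outdir / "metrics.csv")
        log["weights"] = {
            METHOD_LABELS[s.method]: float(w)
            for s, w in zip(specs, ensemble.weights)
        }
        return {"metrics": metrics, "ensemble": ensemble}

    classification = stage("classify", _classify)
    artifacts["metrics"] = classification["metrics"]
    artifacts["ensemble"] = classification["ensemble"]

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return artifacts


def compare_reports(reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Column-wise means over one or more metrics tables, rounded to 2 decimals.

    Rows from all reports are pooled, so passing the per-dataset tables of
    several classification runs reproduces grid summaries such as "average
    CCR over all individual models and datasets".
    """
    if not reports:
        raise ValueError("need at least one report")
    columns = list(reports[0].columns)
    for r in reports[1:]:
        if list(r.columns) != columns:
            raise ValueError("reports have inconsistent columns")
    pooled = pd.concat(reports, axis=0)
    return pooled.mean(axis=0).round(2).to_frame(name="mean").T
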