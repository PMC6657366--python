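"""End-to-end workflows: diagnosis (MS vs control) and course
classification (remitting vs non-remitting).

Both workflows share the same spine: assemble cohorts (generated, loaded, or
reconstructed from summary statistics) -> shuffle/split -> balance the
training set by majority-class partition -> fit one voting ensemble per
model family -> evaluate on the held-out test set. A manifest records every
seed, record count and output-file hash so the bookkeeping
(e.g. 910+199 -> 900 train / 209 test -> 5 x 300 balanced subsets) is
auditable after the fact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import assembly, ensemble as ens, evaluation, models, reconstruct, synthetic
from .cohort import (
    STATUS_MS,
    class_counts,
    concat_cohorts,
    read_cohort_csv,
    with_remitting_labels,
)

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES = list(models.FAMILIES)


@dataclass
class RunConfig:
    """Everything one workflow run needs, from a single document."""

    cohorts: List[dict]                  # source descriptors, see _load_cohorts
    feature_set: str = "target_1_1"
    families: Sequence[str] = tuple(DEFAULT_FAMILIES)
    split: Optional[assembly.SplitSpec] = None
    subset_count: Optional[int] = None   # override ceil(maj/min)
    k: int = 6
    repeats: int = 3
    seed: int = 0
    outdir: Optional[str] = None
    treatment_filter: str = "all"        # 'all' or 'untreated'
    tie_positive: bool = True
    ensemble_score: str = "vote_fraction"  # or 'mean_score'

    def __post_init__(self) -> None:
        if self.feature_set not in models.FEATURE_SETS:
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        bad = set(self.families) - set(models.FAMILIES)
        if bad:
            raise ValueError(f"unknown model families: {sorted(bad)}")
        if self.treatment_filter not in ("all", "untreated"):
            raise ValueError("treatment_filter must be 'all' or 'untreated'")
        if self.ensemble_score not in ("vote_fraction", "mean_score"):
            raise ValueError("ensemble_score must be vote_fraction or mean_score")


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    split = doc.pop("split", None)
    cfg = RunConfig(**doc)
    if split is not None:
        cfg.split = assembly.SplitSpec(**split)
    return cfg


def cohort_spec_from_dict(doc: dict) -> synthetic.CohortSpec:
    """Build a CohortSpec from a config mapping.

    Cytokine specs may be given explicitly under ``cytokine_specs`` or via a
    shorthand: ``panel_direction`` ('usa'/'russian') and ``effect_size``.
    """
    doc = dict(doc)
    if "cytokine_specs" in doc:
        doc["cytokine_specs"] = [
            synthetic.CytokineEffectSpec(**c) for c in doc["cytokine_specs"]]
    else:
        direction = doc.pop("panel_direction", "russian")
        effect = doc.pop("effect_size", synthetic.DEFAULT_EFFECT_SIZE)
        family = doc.pop("distribution_family", "lognormal")
        panel = doc.pop("panel", None)
        doc["cytokine_specs"] = synthetic.default_cytokine_specs(
            direction, effect, panel=panel, distribution_family=family)
    return synthetic.CohortSpec(**doc)


def _load_cohorts(config: RunConfig) -> pd.DataFrame:
    """Materialise every cohort source and stack them.

    Each descriptor is one of
      {"generate": {...CohortSpec fields...}}
      {"cohort_csv": path}
      {"summary_csv": path, "reconstruction": {...ReconstructionConfig...}}
    """
    tables = []
    for i, src in enumerate(config.cohorts):
        if "generate" in src:
            spec_doc = dict(src["generate"])
            spec_doc.setdefault("seed", config.seed + 10 * (i + 1))
            tables.append(synthetic.generate_cohort(cohort_spec_from_dict(spec_doc)))
        elif "cohort_csv" in src:
            tables.append(read_cohort_csv(src["cohort_csv"]))
        elif "summary_csv" in src:
            stats = reconstruct.read_summary_csv(src["summary_csv"])
            rc_doc = dict(src.get("reconstruction", {}))
            rc_doc.setdefault("seed", config.seed + 10 * (i + 1) + 5)
            tables.append(reconstruct.reconstruct_cohort(
                stats, reconstruct.ReconstructionConfig(**rc_doc)))
        else:
            raise ValueError(f"cohort source {i} has no recognised kind: {src}")
    return concat_cohorts(tables)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _report_row(family: str, report: evaluation.MetricReport) -> dict:
    return {
        "model": family,
        "gini": report.gini,
        "accuracy": report.accuracy,
        "auc": report.auc,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "tp": report.counts.tp, "tn": report.counts.tn,
        "fp": report.counts.fp, "fn": report.counts.fn,
    }


def _run_workflow(
    config: RunConfig, table: pd.DataFrame, features: models.FeatureSet,
) -> Tuple[dict, Dict[str, evaluation.MetricReport]]:
    """The shared split -> balance -> ensembles -> evaluate spine."""
    split = config.split or assembly.SplitSpec(
        mode="by_fraction", train_fraction=0.7,
        label_column=features.label_column,
        positive_label=features.positive_label,
        seed=config.seed)
    if split.label_column != features.label_column:
        raise ValueError("split label_column does not match the feature set's")

    train, test = assembly.shuffle_and_split(table, split)
    bundle = assembly.balance_by_subsets(
        train, label_column=features.label_column,
        subset_count=config.subset_count, seed=config.seed + 1)
    logger.info("split: %d train / %d test; %d balanced subsets of sizes %s",
                len(train), len(test), bundle.subset_count,
                [len(s) for s in bundle.subsets])

    truth = (test[features.label_column] == features.positive_label
             ).astype(int).to_numpy()
    manifest = {
        "seed": config.seed,
        "feature_set": features.name,
        "label_column": features.label_column,
        "input_counts": class_counts(table, features.label_column),
        "train_counts": class_counts(train, features.label_column),
        "test_counts": class_counts(test, features.label_column),
        "n_train": len(train),
        "n_test": len(test),
        "subset_count": bundle.subset_count,
        "subset_sizes": [len(s) for s in bundle.subsets],
        "families": list(config.families),
        "outputs": {},
    }

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    reports: Dict[str, evaluation.MetricReport] = {}
    rows = []
    for family in config.families:
        mc = models.ModelConfig(family=family, seed=config.seed + 2)
        trained = ens.fit_ensemble(bundle, mc, features,
                                   tie_positive=config.tie_positive)
        result = ens.predict(trained, test)
        scores = (result.vote_fraction if config.ensemble_score == "vote_fraction"
                  else result.mean_score)
        report, curve = evaluation.evaluate_predictions(result.labels, scores, truth)
        reports[family] = report
        rows.append(_report_row(family, report))
        if outdir:
            pred_path = outdir / f"predictions_{family}.csv"
            ens.predictions_frame(test, result, features).to_csv(
                pred_path, index=False)
            roc_path = outdir / f"roc_{family}.csv"
            curve.to_frame().to_csv(roc_path, index=False)
            manifest["outputs"][pred_path.name] = _sha256(pred_path)
            manifest["outputs"][roc_path.name] = _sha256(roc_path)

    metrics_table = pd.DataFrame(
        rows, columns=["model", "gini", "accuracy", "auc", "sensitivity",
                       "specificity", "tp", "tn", "fp", "fn"])
    if outdir:
        mpath = outdir / "metrics.csv"
        metrics_table.to_csv(mpath, index=False)
        manifest["outputs"][mpath.name] = _sha256(mpath)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    manifest["metrics"] = metrics_table
    return manifest, reports


def run_prediction_workflow(
    config: RunConfig,
) -> Tuple[dict, Dict[str, evaluation.MetricReport]]:
    """Diagnosis workflow: MS vs control on a cytokine(+demographic) panel."""
    features = models.FEATURE_SETS[config.feature_set]
    if features.label_column != "status":
        raise ValueError(
            f"feature set {features.name!r} targets {features.label_column!r}; "
            "the prediction workflow needs a disease-status feature set")
    table = _load_cohorts(config)
    table = _apply_treatment_filter(table, config.treatment_filter)
    return _run_workflow(config, table, features)


def run_classification_workflow(
    config: RunConfig,
) -> Tuple[dict, Dict[str, evaluation.MetricReport]]:
    """Course workflow: remitting vs non-remitting among MS records."""
    features = models.FEATURE_SETS[config.feature_set]
    if features.label_column != "remitting":
        raise ValueError(
            f"feature set {features.name!r} targets {features.label_column!r}; "
            "the classification workflow needs a remitting-label feature set")
    table = _load_cohorts(config)
    table = table[table["status"] == STATUS_MS]
    table = _apply_treatment_filter(table, config.treatment_filter)
    table = with_remitting_labels(table)
    clinical = [c for c in features.columns if c in
                ("age", "gender", "edss", "msss", "duration")]
    complete = table.dropna(subset=clinical)
    if len(complete) < len(table):
        logger.info("dropped %d MS records with incomplete clinical covariates",
                    len(table) - len(complete))
    return _run_workflow(config, complete.reset_index(drop=True), features)


def _apply_treatment_filter(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode == "untreated":
        keep = ~((table["status"] == STATUS_MS) & (table["treatment"] == 1))
        logger.info("treatment filter: kept %d of %d records",
                    int(keep.sum()), len(table))
        return table[keep].reset_index(drop=True)
    return table


def ensemble_fold_accuracy(family: str, features: models.FeatureSet,
                           subset_count: Optional[int] = None,
                           tie_positive: bool = True):
    """Build the fold pipeline used by repeated k-fold CV: balance the fold's
    training part, fit one ensemble, return test accuracy in percent."""
    def run(train: pd.DataFrame, test: pd.DataFrame, fold_seed: int) -> float:
        bundle = assembly.balance_by_subsets(
            train, label_column=features.label_column,
            subset_count=subset_count, seed=fold_seed)
        mc = models.ModelConfig(family=family, seed=fold_seed)
        trained = ens.fit_ensemble(bundle, mc, features,
                                   tie_positive=tie_positive)
        result = ens.predict(trained, test)
        truth = (test[features.label_column]
                 == features.positive_label).astype(int).to_numpy()
        counts = evaluation.confusion(result.labels, truth)
        return evaluation.metrics(counts).accuracy
    return run


def run_repeated_cv(config: RunConfig, family: str = "random_forest",
                    robustness_sd_threshold: float = 5.0) -> evaluation.CVReport:
    """Repeated k-fold CV of the full balance+ensemble pipeline."""
    features = models.FEATURE_SETS[config.feature_set]
    table = _load_cohorts(config)
    if features.label_column == "remitting":
        table = with_remitting_labels(table[table["status"] == STATUS_MS])
    table = _apply_treatment_filter(table, config.treatment_filter)
    return evaluation.repeated_kfold(
        table.reset_index(drop=True),
        ensemble_fold_accuracy(family, features, config.subset_count,
                               config.tie_positive),
        k=config.k, repeats=config.repeats,
        label_column=features.label_column, seed=config.seed,
        robustness_sd_threshold=robustness_sd_threshold)
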