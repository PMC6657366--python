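"""Uniform train/score contract over the four classifier families.

Model internals are delegated to scikit-learn; what this module owns is the
contract (deterministic fits, scores in [0, 1], leakage-safe preprocessing
fitted on training data only) and the mapping of the published tuning
parameters onto the back-end:

  svm_rbf       SVC, radial-basis kernel, Platt-scaled probabilities
  decision_tree DecisionTreeClassifier, min_samples_split=20, max_depth=30
  random_forest RandomForestClassifier, max_features=2 (mtry), 500 trees;
                the score is the fraction of trees voting positive
  neural_net    MLPClassifier, one hidden layer of 5 logistic units

Scale-sensitive families (svm_rbf, neural_net) see min-max scaled features;
tree families consume raw features. Gender is encoded as a single 0/1
indicator (F=1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import CORE_CYTOKINES, EXTENDED_CYTOKINES

logger = logging.getLogger(__name__)

FAMILIES = ("svm_rbf", "decision_tree", "random_forest", "neural_net")

#: Published tuning parameters, plus defaults the source leaves unstated
#: (SVM cost, NN optimisation); unstated values are logged at fit time.
DEFAULT_HYPERPARAMS: Dict[str, Dict] = {
    "svm_rbf": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "decision_tree": {"min_samples_split": 20, "max_depth": 30},
    "random_forest": {"n_estimators": 500, "max_features": 2},
    "neural_net": {"hidden_layer_sizes": (5,), "activation": "logistic",
                   "solver": "lbfgs", "max_iter": 1000},
}

SCALED_FAMILIES = ("svm_rbf", "neural_net")


@dataclass(frozen=True)
class ModelConfig:
    """One classifier family with its hyper-parameters and seed."""

    family: str
    hyperparams: Optional[Dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")

    def resolved_hyperparams(self) -> Dict:
        params = dict(DEFAULT_HYPERPARAMS[self.family])
        if self.hyperparams:
            params.update(self.hyperparams)
        return params


@dataclass(frozen=True)
class FeatureSet:
    """Named feature list plus the label column it predicts."""

    name: str
    columns: Sequence[str]
    label_column: str
    positive_label: str


def _diagnosis_fs(name: str, panel: List[str], extra: List[str]) -> FeatureSet:
    return FeatureSet(name=name, columns=tuple(panel + extra),
                      label_column="status", positive_label="MS")


#: The built-in feature sets: cytokines alone, + demographics, and
#: + clinical scores for the remitting / non-remitting task; _ext variants
#: add IL-6 and IFN-alpha to the panel.
FEATURE_SETS: Dict[str, FeatureSet] = {
    "target_1_1": _diagnosis_fs("target_1_1", CORE_CYTOKINES, []),
    "target_1_2": _diagnosis_fs("target_1_2", CORE_CYTOKINES, ["age", "gender"]),
    "target_1_2_ext": _diagnosis_fs("target_1_2_ext", EXTENDED_CYTOKINES,
                                    ["age", "gender"]),
    "target_2": FeatureSet(
        name="target_2",
        columns=tuple(CORE_CYTOKINES + ["age", "gender", "edss", "msss", "duration"]),
        label_column="remitting", positive_label="remitting"),
    "target_2_ext": FeatureSet(
        name="target_2_ext",
        columns=tuple(EXTENDED_CYTOKINES + ["age", "gender", "edss", "msss",
                                            "duration"]),
        label_column="remitting", positive_label="remitting"),
}

_GENDER_CODE = {"F": 1.0, "M": 0.0}


@dataclass
class TrainedModel:
    """A fitted classifier plus its preprocessing state."""

    config: ModelConfig
    feature_set: FeatureSet
    estimator: object
    scaler: Optional[MinMaxScaler]
    columns: List[str]


def _encode_features(table: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing feature columns: {missing}")
    X = np.empty((len(table), len(columns)), dtype=float)
    for j, col in enumerate(columns):
        if col == "gender":
            vals = table[col].astype(str)
            unseen = set(vals) - set(_GENDER_CODE)
            if unseen:
                raise ValueError(f"unseen gender levels: {sorted(unseen)}")
            X[:, j] = vals.map(_GENDER_CODE).to_numpy()
        else:
            X[:, j] = pd.to_numeric(table[col], errors="coerce").to_numpy()
    if np.isnan(X).any():
        rows = table.index[np.isnan(X).any(axis=1)].tolist()
        raise ValueError(f"missing values in feature columns at rows {rows[:10]}")
    return X


def _build_estimator(config: ModelConfig):
    params = config.resolved_hyperparams()
    fam = config.family
    if fam == "svm_rbf":
        logger.info("svm_rbf: C=%s, gamma=%s (back-end defaults where unstated)",
                    params["C"], params["gamma"])
        return SVC(probability=True, random_state=config.seed, **params)
    if fam == "decision_tree":
        return DecisionTreeClassifier(random_state=config.seed, **params)
    if fam == "random_forest":
        return RandomForestClassifier(random_state=config.seed, n_jobs=1, **params)
    if fam == "neural_net":
        hp = dict(params)
        hp["hidden_layer_sizes"] = tuple(hp["hidden_layer_sizes"])
        logger.info("neural_net: solver=%s, max_iter=%s (unstated in source, logged)",
                    hp["solver"], hp["max_iter"])
        return MLPClassifier(random_state=config.seed, **hp)
    raise AssertionError(fam)


def fit(table: pd.DataFrame, config: ModelConfig,
        features: FeatureSet) -> TrainedModel:
    """Fit one classifier on *table* under the uniform contract.

    Preprocessing (scaling, gender encoding) is learned from *table* only.
    The label is binarised with features.positive_label -> 1.
    """
    if features.label_column not in table.columns:
        raise ValueError(f"table is missing label column {features.label_column!r}")
    y_raw = table[features.label_column]
    classes = sorted(y_raw.unique())
    if len(classes) != 2:
        raise ValueError(
            f"training label must be binary with both classes present, "
            f"got {classes}")
    if features.positive_label not in classes:
        raise ValueError(
            f"positive label {features.positive_label!r} absent from training data")
    y = (y_raw == features.positive_label).astype(int).to_numpy()

    X = _encode_features(table, features.columns)
    scaler = None
    if config.family in SCALED_FAMILIES:
        scaler = MinMaxScaler()
        X = scaler.fit_transform(X)

    # mtry cannot exceed the number of features actually offered
    cfg = config
    if config.family == "random_forest":
        params = config.resolved_hyperparams()
        if params["max_features"] > len(features.columns):
            params["max_features"] = len(features.columns)
            cfg = ModelConfig(config.family, params, config.seed)

    est = _build_estimator(cfg)
    import warnings

    with warnings.catch_warnings():
        # Platt scaling via SVC(probability=True) is the classic route;
        # newer sklearn nudges toward CalibratedClassifierCV at fit time.
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(X, y)
    return TrainedModel(config=cfg, feature_set=features, estimator=est,
                        scaler=scaler, columns=list(features.columns))


def predict_score(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Score every row of *table*: P(positive class), in [0, 1].

    For the random forest the score is the fraction of trees whose own
    prediction is the positive class, so it lives on the grid
    {0, 1/n_trees, ..., 1}.
    """
    if table.empty:
        return np.empty(0, dtype=float)
    X = _encode_features(table, model.columns)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    est = model.estimator
    if isinstance(est, RandomForestClassifier):
        votes = np.stack([tree.predict(X) for tree in est.estimators_])
        return votes.mean(axis=0)
    proba = est.predict_proba(X)
    pos = list(est.classes_).index(1)
    return proba[:, pos]


def predict_label(model: TrainedModel, table: pd.DataFrame,
                  threshold: float = 0.5) -> np.ndarray:
    """Hard labels by thresholding the score at *threshold* (>= is positive)."""
    return (predict_score(model, table) >= threshold).astype(int)


def _config_fingerprint(config: ModelConfig, features: FeatureSet) -> str:
    import hashlib
    import json

    doc = {"family": config.family, "seed": config.seed,
           "hyperparams": {k: str(v) for k, v in
                           sorted(config.resolved_hyperparams().items())},
           "features": list(features.columns),
           "label": features.label_column}
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def save_model(model: TrainedModel, path) -> str:
    """Persist a trained model with its preprocessing state and a config
    fingerprint; returns the fingerprint."""
    import pickle

    fp = _config_fingerprint(model.config, model.feature_set)
    with open(path, "wb") as fh:
        pickle.dump({"fingerprint": fp, "model": model}, fh)
    return fp


def load_model(path, expect_fingerprint: Optional[str] = None) -> TrainedModel:
    """Load a model saved by :func:`save_model`, optionally checking its
    config fingerprint."""
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    stored = payload["fingerprint"]
    recomputed = _config_fingerprint(payload["model"].config,
                                     payload["model"].feature_set)
    if stored != recomputed:
        raise ValueError("model file fingerprint does not match its config")
    if expect_fingerprint is not None and stored != expect_fingerprint:
        raise ValueError("model fingerprint differs from the expected one")
    return payload["model"]
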