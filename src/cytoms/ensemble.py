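"""Majority-voting ensemble over balanced training subsets.

One classifier is trained per balanced subset; at prediction time each
member casts a hard vote (its 0.5-thresholded label) and the ensemble label
is the majority. The vote fraction (votes for the positive class divided by
member count) doubles as the ensemble's continuous score for ROC analysis;
averaging member probabilities is available as an alternative.

Tie rule (relevant only for even member counts): ties go to the positive
class — in a screening setting a missed case costs more than a false alarm.
Configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .assembly import BalancedBundle
from .models import FeatureSet, ModelConfig, TrainedModel, fit, predict_score


@dataclass
class TrainedEnsemble:
    members: List[TrainedModel]
    feature_set: FeatureSet
    tie_positive: bool = True

    @property
    def member_count(self) -> int:
        return len(self.members)


@dataclass
class PredictionResult:
    """Per-record ensemble outputs, aligned with the scored table."""

    votes_positive: np.ndarray  # int, in [0, member_count]
    vote_fraction: np.ndarray   # votes_positive / member_count
    mean_score: np.ndarray      # average of member probabilities
    labels: np.ndarray          # 0/1 ensemble decision

    def __len__(self) -> int:
        return len(self.labels)


def combine_votes(votes_positive: np.ndarray, member_count: int,
                  tie_positive: bool = True) -> np.ndarray:
    """Majority decision from positive-vote counts; ties per *tie_positive*."""
    v2 = 2 * np.asarray(votes_positive)
    if tie_positive:
        return (v2 >= member_count).astype(int)
    return (v2 > member_count).astype(int)


def fit_ensemble(bundle: BalancedBundle, config: ModelConfig,
                 features: FeatureSet,
                 tie_positive: bool = True) -> TrainedEnsemble:
    """Train one member per balanced subset.

    Member seeds are derived deterministically from the master seed so two
    runs with the same configuration produce identical ensembles.
    """
    if bundle.subset_count < 1:
        raise ValueError("bundle has no subsets")
    members = []
    for i, subset in enumerate(bundle.subsets):
        member_cfg = ModelConfig(config.family, config.hyperparams,
                                 seed=config.seed + 1000 * (i + 1))
        try:
            members.append(fit(subset, member_cfg, features))
        except Exception as exc:
            raise RuntimeError(f"fit failed on balanced subset {i}: {exc}") from exc
    return TrainedEnsemble(members=members, feature_set=features,
                           tie_positive=tie_positive)


def predict(ensemble: TrainedEnsemble, table: pd.DataFrame) -> PredictionResult:
    """Score *table* with every member and combine by majority vote."""
    m = ensemble.member_count
    if table.empty:
        empty = np.empty(0)
        return PredictionResult(empty.astype(int), empty, empty, empty.astype(int))
    scores = np.stack([predict_score(mod, table) for mod in ensemble.members])
    member_votes = (scores >= 0.5).astype(int)
    votes_positive = member_votes.sum(axis=0)
    labels = combine_votes(votes_positive, m, ensemble.tie_positive)
    return PredictionResult(
        votes_positive=votes_positive,
        vote_fraction=votes_positive / m,
        mean_score=scores.mean(axis=0),
        labels=labels,
    )


def predictions_frame(table: pd.DataFrame, result: PredictionResult,
                      feature_set: FeatureSet) -> pd.DataFrame:
    """Tabulate per-subject ensemble predictions next to the true label."""
    truth = (table[feature_set.label_column]
             == feature_set.positive_label).astype(int)
    return pd.DataFrame({
        "subject_id": table["subject_id"].to_numpy(),
        "votes_positive": result.votes_positive,
        "vote_fraction": result.vote_fraction,
        "mean_score": result.mean_score,
        "label": result.labels,
        "true_label": truth.to_numpy(),
    })
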