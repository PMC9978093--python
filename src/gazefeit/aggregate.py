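"""Participant-level aggregation of per-trial predictions.

A participant's trials are summarized as an ordered binary vector indexed by
stimulus face number (not presentation order, which was randomized).  Two
aggregators produce the final diagnosis:

* hard voting — majority rule over the vector;
* a random forest trained on the training participants' vectors — the
  weighted aggregator.  Because different stimuli (emotions) separate the
  groups unequally, the forest implicitly weights each face by its
  informativeness, and its averaged feature importances read out which
  stimuli drive the classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .stimuli import face_emotion_map

FOREST_N_TREES = 500


def prediction_vector(trial_predictions: pd.Series | dict[int, int], population: str) -> np.ndarray:
    """Order per-trial predictions by face number into a fixed-length vector."""
    faces = sorted(face_emotion_map(population))
    mapping = dict(trial_predictions) if not isinstance(trial_predictions, pd.Series) else trial_predictions.to_dict()
    missing = [f for f in faces if f not in mapping]
    if missing:
        raise ValueError(f"missing trial predictions for faces {missing}")
    return np.array([int(mapping[f]) for f in faces])


def hard_vote(vector: np.ndarray) -> int:
    """Majority label; an exact tie (even-length vectors) goes to the
    positive/disorder class."""
    v = np.asarray(vector)
    if np.isnan(v.astype(float)).any():
        raise ValueError("prediction vector has missing entries")
    pos = int(v.sum())
    return 1 if pos * 2 >= len(v) else 0


def fit_weighting_forest(vectors: np.ndarray, labels: np.ndarray, seed: int = 0) -> RandomForestClassifier:
    """Random forest over the (participants x faces) prediction matrix."""
    vectors = np.asarray(vectors)
    labels = np.asarray(labels)
    if len(vectors) < 2 or len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 training participants with both classes present")
    forest = RandomForestClassifier(
        n_estimators=FOREST_N_TREES, criterion="gini", max_depth=None, random_state=seed
    )
    forest.fit(vectors, labels)
    return forest


def predict_participant(forest: RandomForestClassifier, vector: np.ndarray) -> int:
    vector = np.asarray(vector)
    if vector.shape[0] != forest.n_features_in_:
        raise ValueError(f"vector length {vector.shape[0]} != forest features {forest.n_features_in_}")
    return int(forest.predict(vector.reshape(1, -1))[0])


def forest_importances(forest: RandomForestClassifier) -> np.ndarray:
    """Normalized importances; a forest with no splits falls back to uniform."""
    imp = np.asarray(forest.feature_importances_, float)
    total = imp.sum()
    if total <= 0:
        return np.full(len(imp), 1.0 / len(imp))
    return imp / total


def average_importances(forests, population: str) -> pd.DataFrame:
    """Arithmetic mean of per-face importances across cross-validation folds,
    annotated with each face's emotion."""
    forests = list(forests)
    if not forests:
        raise ValueError("need at least one forest")
    mats = [forest_importances(f) for f in forests]
    lengths = {len(m) for m in mats}
    if len(lengths) != 1:
        raise ValueError("inconsistent importance lengths across folds")
    mean_imp = np.mean(mats, axis=0)
    fmap = face_emotion_map(population)
    faces = sorted(fmap)
    if len(faces) != len(mean_imp):
        raise ValueError("importance length does not match the stimulus bank")
    return pd.DataFrame(
        {"face": faces, "emotion": [fmap[f] for f in faces], "mean_importance": mean_imp}
    )
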