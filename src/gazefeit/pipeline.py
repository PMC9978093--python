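"""Glue between cohorts and the modeling stages.

Turns a simulated (or loaded) cohort into the trial-feature table used by the
statistics stage and into `TrialDataset` objects for the two classifier
architectures, restricted to one pairwise problem (control vs. one disorder
group).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import DisplayGeometry, EventConfig, trial_features
from .evaluate import TrialDataset
from .events import cyclopean_points
from .heatmap import HeatmapConfig, blur, build_hit_map, downscaled_channel
from .models import BASELINE_FEATURES
from .stimuli import stimulus_image
from .synthgaze import Cohort


def cohort_features(
    cohort: Cohort,
    config: EventConfig = EventConfig(),
    geom: DisplayGeometry = DisplayGeometry(),
) -> pd.DataFrame:
    """One row of trial features per trial, joined with the manifest."""
    rows = []
    for rec in cohort.manifest.itertuples(index=False):
        feats = trial_features(cohort.trials[rec.trial_id], cohort.aois[rec.face_number], config, geom)
        row = {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "trial_id": rec.trial_id,
            "face_number": rec.face_number,
            "emotion": rec.emotion,
        }
        row.update(feats.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def _pairwise(features: pd.DataFrame, positive_group: str) -> pd.DataFrame:
    df = features[features["group"].isin(["control", positive_group])].copy()
    if df["group"].nunique() < 2:
        raise ValueError(f"cohort lacks control or {positive_group!r} participants")
    df["label"] = (df["group"] == positive_group).astype(int)
    return df


def baseline_dataset(features: pd.DataFrame, positive_group: str, population: str) -> TrialDataset:
    """Raw (unscaled) 3-feature rows; scaling happens per cross-validation fold."""
    df = _pairwise(features, positive_group)
    return TrialDataset(
        X=df[list(BASELINE_FEATURES)].to_numpy(float),
        y=df["label"].to_numpy(int),
        participants=df["participant_id"].to_numpy(),
        face_numbers=df["face_number"].to_numpy(int),
        population=population,
        arch_kind="baseline",
    )


def cnn_dataset(
    cohort: Cohort,
    positive_group: str,
    config: HeatmapConfig = HeatmapConfig(),
) -> TrialDataset:
    """Precomputed 2-channel heat-map inputs (fold-independent, so computed once)."""
    df = _pairwise(cohort.manifest, positive_group)
    # The stimulus channel is identical for every trial showing the same face.
    stim_chan = {
        f: downscaled_channel(
            stimulus_image(cohort.population, f, config.native_resolution),
            config, cohort.aois[f].face_bbox,
        )
        for f in df["face_number"].unique()
    }
    inputs = []
    for rec in df.itertuples(index=False):
        hit = build_hit_map(cyclopean_points(cohort.trials[rec.trial_id]), config.native_resolution)
        heat = downscaled_channel(
            blur(hit, config.sigma_px, config.truncate), config, cohort.aois[rec.face_number].face_bbox
        )
        inputs.append(np.stack([stim_chan[rec.face_number], heat]))
    X = np.stack(inputs)
    return TrialDataset(
        X=X,
        y=df["label"].to_numpy(int),
        participants=df["participant_id"].to_numpy(),
        face_numbers=df["face_number"].to_numpy(int),
        population=cohort.population,
        arch_kind="cnn",
    )
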