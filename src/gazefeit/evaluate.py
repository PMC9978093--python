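"""Nested leave-one-participant-out evaluation and confusion metrics.

Each fold holds out one participant entirely: feature scaling statistics,
learning-rate selection, the trial classifier, and the weighting forest are
all fitted on the remaining participants only.  The held-out participant's
trials are then classified, aggregated by hard voting and by the forest, and
recorded.  Metrics follow the usual confusion-matrix definitions with the
disorder group as the positive class and controls as the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from . import aggregate as agg
from .models import ArchConfig, BaselineScaler, TrainConfig, predict_trials, train


@dataclass
class TrialDataset:
    """Per-trial inputs for one pairwise classification problem.

    ``X`` holds either (n, 3) raw baseline feature rows (scaled per fold) or
    (n, 2, 34, 34) model inputs; ``y`` is the participant diagnosis inherited
    by each trial (1 = disorder, 0 = control).
    """

    X: np.ndarray
    y: np.ndarray
    participants: np.ndarray
    face_numbers: np.ndarray
    population: str
    arch_kind: str  # "baseline" | "cnn"

    def __post_init__(self):
        n = len(self.X)
        if not (len(self.y) == len(self.participants) == len(self.face_numbers) == n):
            raise ValueError("misaligned trial arrays")

    def participant_labels(self) -> dict[str, int]:
        return {p: int(self.y[self.participants == p][0]) for p in np.unique(self.participants)}


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    counts: ConfusionCounts
    binomial_p: float | None = None
    predictions: pd.DataFrame | None = None


def confusion_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Exact rational evaluation of accuracy / sensitivity / specificity.

    A metric whose denominator is zero is reported as None rather than
    raising, so degenerate one-class evaluations stay auditable.
    """

    def ratio(num: int, den: int) -> float | None:
        return float(Fraction(num, den)) if den > 0 else None

    return MetricsReport(
        accuracy=ratio(counts.TP + counts.TN, counts.total),
        sensitivity=ratio(counts.TP, counts.TP + counts.FN),
        specificity=ratio(counts.TN, counts.TN + counts.FP),
        counts=counts,
    )


def counts_from_predictions(df: pd.DataFrame, pred_col: str = "prediction") -> ConfusionCounts:
    y, p = df["true_label"].to_numpy(int), df[pred_col].to_numpy(int)
    return ConfusionCounts(
        TP=int(((y == 1) & (p == 1)).sum()),
        TN=int(((y == 0) & (p == 0)).sum()),
        FP=int(((y == 0) & (p == 1)).sum()),
        FN=int(((y == 1) & (p == 0)).sum()),
    )


def binomial_vs_chance(n_correct: int, n_total: int, chance_rate: float = 0.5,
                       alternative: str = "two-sided") -> float:
    """Exact binomial tail probability against a fixed chance rate.

    Two-sided p doubles the smaller tail and caps at 1 (the convention is
    recorded so results are auditable; it differs from the minlike convention
    some packages default to).
    """
    if not (0 <= n_correct <= n_total) or not (0 < chance_rate < 1):
        raise ValueError("invalid binomial test inputs")
    dist = stats.binom(n_total, chance_rate)
    lower = float(dist.cdf(n_correct))
    upper = float(dist.sf(n_correct - 1))
    if alternative == "greater":
        return upper
    if alternative == "less":
        return lower
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class LopoResult:
    predictions: pd.DataFrame  # participant_id, true_label, pred_hard, pred_forest
    forests: list = field(default_factory=list)
    fold_failures: list = field(default_factory=list)
    fold_train_pids: dict = field(default_factory=dict)
    logs: dict = field(default_factory=dict)


def nested_lopo(
    dataset: TrialDataset,
    train_cfg: TrainConfig,
    forest_mode: str = "insample",
    seed: int = 0,
) -> LopoResult:
    """Leave-one-participant-out over the cohort; returns per-participant
    predictions for both aggregators plus the per-fold forests.

    ``forest_mode`` controls which first-stage predictions the weighting
    forest is trained on: ``"insample"`` re-applies the fold's trial model to
    its own training trials (mirroring the original procedure), ``"oof"``
    uses inner out-of-fold predictions to avoid optimism.
    """
    if forest_mode not in ("insample", "oof"):
        raise ValueError(f"unknown forest_mode {forest_mode!r}")
    labels = dataset.participant_labels()
    pids = sorted(labels)
    if len(pids) < 3 or len(set(labels.values())) < 2:
        raise ValueError("need >= 3 participants with both classes present")
    arch = ArchConfig(kind=dataset.arch_kind)
    rows, forests, failures, fold_pids, logs = [], [], [], {}, {}
    for fold, test_pid in enumerate(pids):
        held = dataset.participants == test_pid
        tr_y = dataset.y[~held]
        if len(np.unique(tr_y)) < 2:
            failures.append({"participant_id": test_pid, "true_label": labels[test_pid],
                             "reason": "single-class training fold"})
            continue
        fold_pids[test_pid] = sorted(set(dataset.participants[~held]))
        fold_seed = (seed * 1009 + fold) % (2**31)
        fold_cfg = TrainConfig(
            max_epochs=train_cfg.max_epochs,
            early_stop_patience=train_cfg.early_stop_patience,
            lr_grid=train_cfg.lr_grid,
            val_fraction=train_cfg.val_fraction,
            batch_size=train_cfg.batch_size,
            seed=fold_seed,
            inner_fold_cap=train_cfg.inner_fold_cap,
            balanced_loss=train_cfg.balanced_loss,
            balance_training=train_cfg.balance_training,
        )
        if dataset.arch_kind == "baseline":
            scaler = BaselineScaler().fit(dataset.X[~held])
            X_all = scaler.transform(dataset.X)
        else:
            X_all = dataset.X
        model = train(X_all[~held], tr_y, dataset.participants[~held], arch, fold_cfg)
        logs[test_pid] = model.log

        if forest_mode == "insample":
            first_stage = predict_trials(model, X_all[~held])
            fs_participants = dataset.participants[~held]
            fs_faces = dataset.face_numbers[~held]
        else:
            first_stage, fs_participants, fs_faces = _oof_first_stage(
                dataset, X_all, held, arch, fold_cfg
            )
        vec_rows, vec_labels = [], []
        for pid in fold_pids[test_pid]:
            mask = fs_participants == pid
            vec = agg.prediction_vector(
                dict(zip(fs_faces[mask], first_stage[mask])), dataset.population
            )
            vec_rows.append(vec)
            vec_labels.append(labels[pid])
        # Balance the forest's training matrix: the fold is tilted against the
        # held-out class by construction, and an unbalanced forest drifts
        # toward the training majority on no-signal data.
        bal_rows, bal_labels = _balance_rows(
            np.array(vec_rows), np.array(vec_labels), fold_seed
        )
        forest = agg.fit_weighting_forest(bal_rows, bal_labels, seed=fold_seed)
        forests.append(forest)

        test_pred = predict_trials(model, X_all[held])
        test_vec = agg.prediction_vector(
            dict(zip(dataset.face_numbers[held], test_pred)), dataset.population
        )
        rows.append(
            {
                "participant_id": test_pid,
                "true_label": labels[test_pid],
                "pred_hard": agg.hard_vote(test_vec),
                "pred_forest": agg.predict_participant(forest, test_vec),
            }
        )
    predictions = pd.DataFrame(rows)
    return LopoResult(predictions, forests, failures, fold_pids, logs)


def _balance_rows(rows: np.ndarray, labels: np.ndarray, seed: int):
    """Subsample majority-class rows to the minority count (deterministic)."""
    counts = np.bincount(labels, minlength=2)
    n_keep = counts.min()
    rng = np.random.default_rng(seed)
    kept = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(labels == cls)
        kept.append(rng.permutation(cls_idx)[:n_keep])
    sel = np.sort(np.concatenate(kept))
    return rows[sel], labels[sel]


def _oof_first_stage(dataset, X_all, held, arch, fold_cfg):
    """Inner-LOPO out-of-fold predictions for the training participants."""
    participants = dataset.participants[~held]
    X_tr, y_tr, faces_tr = X_all[~held], dataset.y[~held], dataset.face_numbers[~held]
    preds = np.zeros(len(y_tr), dtype=int)
    for pid in np.unique(participants):
        inner = participants == pid
        if len(np.unique(y_tr[~inner])) < 2:
            preds[inner] = int(np.bincount(y_tr[~inner]).argmax())
            continue
        m = train(X_tr[~inner], y_tr[~inner], participants[~inner], arch, fold_cfg)
        preds[inner] = predict_trials(m, X_tr[inner])
    return preds, participants, faces_tr


def evaluate_lopo(result: LopoResult, chance_rate: float = 0.5) -> dict[str, MetricsReport]:
    """Confusion metrics and the binomial test for both aggregators.

    Fold failures are counted as errors (the participant is scored as
    misclassified) so totals always reconcile with the cohort size.
    """
    fail_fn = sum(1 for f in result.fold_failures if f["true_label"] == 1)
    fail_fp = sum(1 for f in result.fold_failures if f["true_label"] == 0)
    out = {}
    for agg_name, col in (("hard", "pred_hard"), ("forest", "pred_forest")):
        counts = counts_from_predictions(result.predictions, col)
        counts = ConfusionCounts(counts.TP, counts.TN, counts.FP + fail_fp, counts.FN + fail_fn)
        report = confusion_metrics(counts)
        n_correct = counts.TP + counts.TN
        report.binomial_p = binomial_vs_chance(n_correct, counts.total, chance_rate)
        report.predictions = result.predictions
        out[agg_name] = report
    return out
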