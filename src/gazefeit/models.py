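"""Per-trial binary classifiers and their training protocol.

Two architectures:

* ``baseline`` — a multilayer perceptron on three trial features (total
  fixation-sample count, saccade count, scan-path length), three hidden
  layers of 5 units each;
* ``cnn`` — a small convolutional network on the 2 x 34 x 34 stimulus +
  heat-map input: two 3x3 conv layers (8 then 16 filters), each followed by
  ReLU and 2x2 max pooling, then one fully connected layer with 2 logits.

Both train with Adam on softmax cross-entropy for at most 300 epochs, with
early stopping when the validation loss has not improved for 15 epochs and
restoration of the best-validation weights.  The validation split is at
participant level (8:2, stratified by class), and the learning rate is chosen
by an inner leave-one-participant-out loop over the training participants.
Every trial inherits its participant's diagnosis as its label; the per-trial
problem is deliberately noisy and is resolved at the aggregation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Conv3x3, Dense, Flatten, MaxPool2, Network, ReLU, softmax_cross_entropy

BASELINE_FEATURES = ("fix_anywhere", "n_saccades", "scan_path_length")


@dataclass(frozen=True)
class ArchConfig:
    kind: str = "baseline"  # "baseline" | "cnn"
    baseline_hidden: tuple[int, ...] = (5, 5, 5)
    cnn_filters: tuple[int, ...] = (8, 16)
    input_channels: int = 2
    input_size: int = 34

    def __post_init__(self):
        if self.kind not in ("baseline", "cnn"):
            raise ValueError(f"unknown architecture {self.kind!r}")


@dataclass
class TrainConfig:
    max_epochs: int = 300
    early_stop_patience: int = 15
    lr_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    val_fraction: float = 0.2
    batch_size: int = 32
    seed: int = 0
    inner_fold_cap: int | None = None  # None = full inner LOPO for lr selection
    #: inverse-frequency class weights in the loss; keeps the trial model's
    #: prior neutral when a cross-validation fold is mildly class-imbalanced
    #: (otherwise leave-one-out under no-signal data is biased below chance).
    balanced_loss: bool = True
    #: subsample majority-class training trials to the minority count before
    #: fitting (deterministic under seed).  Leave-one-participant-out folds are
    #: tilted against the held-out class by construction; without balancing,
    #: the trial model's collapse direction tracks that tilt and biases
    #: no-signal accuracy away from chance.
    balance_training: bool = True

    def __post_init__(self):
        if not self.lr_grid:
            raise ValueError("lr_grid must be non-empty")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


class BaselineScaler:
    """Per-feature z-scoring with statistics from training trials only.

    A feature that is constant across the training set maps to 0 (guarded
    divide) rather than blowing up.
    """

    def fit(self, X: np.ndarray) -> "BaselineScaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.constant_ = sd == 0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.mean_) / self.scale_
        Z[:, self.constant_] = 0.0
        return Z.astype(np.float32)


def featurize_baseline(features_df, scaler: BaselineScaler) -> np.ndarray:
    """Trial-feature rows -> scaled (n, 3) baseline inputs."""
    return scaler.transform(features_df[list(BASELINE_FEATURES)].to_numpy(float))


def build_network(arch: ArchConfig, rng: np.random.Generator) -> Network:
    if arch.kind == "baseline":
        layers, n_in = [], len(BASELINE_FEATURES)
        for width in arch.baseline_hidden:
            layers += [Dense(n_in, width, rng), ReLU()]
            n_in = width
        layers.append(Dense(n_in, 2, rng))
        return Network(layers)
    f1, f2 = arch.cnn_filters
    s = arch.input_size
    after = ((s - 2) // 2 - 2) // 2  # two (conv valid, pool 2) stages
    return Network(
        [
            Conv3x3(arch.input_channels, f1, rng),
            ReLU(),
            MaxPool2(),
            Conv3x3(f1, f2, rng),
            ReLU(),
            MaxPool2(),
            Flatten(),
            Dense(f2 * after * after, 2, rng),
        ]
    )


def _participant_split(participants, labels_by_pid, val_fraction, rng):
    """Participant-level stratified train/validation split (8:2 by default)."""
    pids = np.asarray(sorted(set(participants)))
    val = []
    for cls in sorted(set(labels_by_pid.values())):
        cls_pids = [p for p in pids if labels_by_pid[p] == cls]
        # keep at least one training participant of every class
        n_val = min(len(cls_pids) - 1, max(1, int(round(len(cls_pids) * val_fraction))))
        val.extend(rng.permutation(cls_pids)[:n_val])
    val = set(val)
    train = [p for p in pids if p not in val]
    if not train:  # degenerate tiny pools: keep at least one training participant
        train, val = list(val)[:1], set(list(val)[1:])
    return set(train), val


@dataclass
class TrainedModel:
    network: Network
    arch: ArchConfig
    lr: float
    log: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_trials(self, X)


def train(
    X: np.ndarray,
    y: np.ndarray,
    participants,
    arch: ArchConfig,
    cfg: TrainConfig,
    lr: float | None = None,
) -> TrainedModel:
    """Fit one trial classifier with the early-stopping protocol.

    ``participants`` aligns with rows of ``X`` and drives the 8:2
    participant-level validation split.  Deterministic under ``cfg.seed``.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    participants = np.asarray(participants)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    labels_by_pid = {p: int(y[participants == p][0]) for p in set(participants)}
    if len(labels_by_pid) < 2:
        raise ValueError("need at least two participants to train")
    rng = np.random.default_rng(cfg.seed)
    if lr is None:
        lr = cfg.lr_grid[0] if len(cfg.lr_grid) == 1 else select_learning_rate(X, y, participants, arch, cfg)
    train_pids, val_pids = _participant_split(participants, labels_by_pid, cfg.val_fraction, rng)
    tr = np.isin(participants, list(train_pids))
    va = np.isin(participants, list(val_pids))
    net = build_network(arch, rng)
    opt = Adam(net.params, lr=lr)
    best_val, best_weights, best_epoch, stale = np.inf, net.get_weights(), 0, 0
    log = {"train_loss": [], "val_loss": [], "lr": lr}
    idx = np.flatnonzero(tr)
    if cfg.balance_training:
        counts = np.bincount(y[idx], minlength=2)
        n_keep = counts.min()
        kept = []
        for cls in (0, 1):
            cls_idx = idx[y[idx] == cls]
            kept.append(rng.permutation(cls_idx)[:n_keep])
        idx = np.sort(np.concatenate(kept))
    weights = None
    if cfg.balanced_loss:
        counts = np.bincount(y[idx], minlength=2)
        weights = len(idx) / (2.0 * np.maximum(counts, 1))
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            logits = net.forward(X[batch])
            loss, dl = softmax_cross_entropy(logits, y[batch], weights)
            net.backward(dl)
            opt.step(net.grads)
            losses.append(loss)
        log["train_loss"].append(float(np.mean(losses)))
        val_loss, _ = (
            softmax_cross_entropy(net.forward(X[va]), y[va], weights)
            if va.any()
            else (log["train_loss"][-1], None)
        )
        log["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-9:
            best_val, best_weights, best_epoch, stale = val_loss, net.get_weights(), epoch, 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    net.set_weights(best_weights)
    log.update(best_epoch=best_epoch, best_val_loss=float(best_val), epochs_trained=len(log["train_loss"]))
    return TrainedModel(network=net, arch=arch, lr=lr, log=log)


def select_learning_rate(X, y, participants, arch: ArchConfig, cfg: TrainConfig) -> float:
    """Inner leave-one-participant-out grid search; ties go to the smallest lr.

    ``cfg.inner_fold_cap`` optionally subsamples the inner folds (deterministic
    choice) to bound runtime; the default is the full inner loop.
    """
    if len(cfg.lr_grid) == 1:
        return cfg.lr_grid[0]
    participants = np.asarray(participants)
    pids = sorted(set(participants))
    if cfg.inner_fold_cap is not None and len(pids) > cfg.inner_fold_cap:
        sel = np.random.default_rng(cfg.seed).permutation(len(pids))[: cfg.inner_fold_cap]
        pids = [pids[i] for i in sorted(sel)]
    scores = {}
    inner_cfg = TrainConfig(
        max_epochs=cfg.max_epochs,
        early_stop_patience=cfg.early_stop_patience,
        lr_grid=(0.0,),  # placeholder; lr passed explicitly below
        val_fraction=cfg.val_fraction,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
        balanced_loss=cfg.balanced_loss,
        balance_training=cfg.balance_training,
    )
    for lr in sorted(cfg.lr_grid):
        accs = []
        for pid in pids:
            held = participants == pid
            if len(np.unique(y[~held])) < 2:
                continue
            model = train(X[~held], y[~held], participants[~held], arch, inner_cfg, lr=lr)
            accs.append(float((model.predict(X[held]) == y[held]).mean()))
        scores[lr] = float(np.mean(accs)) if accs else 0.0
    best = max(scores.values())
    return min(lr for lr, s in scores.items() if s == best)  # smallest lr wins ties


def predict_trials(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Argmax over the two logits, one binary label per trial."""
    X = np.asarray(X, dtype=np.float32)
    expected = (len(BASELINE_FEATURES),) if model.arch.kind == "baseline" else (
        model.arch.input_channels, model.arch.input_size, model.arch.input_size)
    if X.shape[1:] != expected:
        raise ValueError(f"input shape {X.shape[1:]} does not match model input {expected}")
    return model.network.forward(X).argmax(axis=1)
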