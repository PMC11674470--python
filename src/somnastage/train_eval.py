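"""Training strategy, cross-validation protocols, metrics and experiment
orchestration.

Training uses Adam (learning rate 0.001, weight decay 0.001, AMSGrad) with
a step schedule halving the rate every 10 epochs, and a weighted
cross-entropy whose class weights are computed from the *training* split
of each fold (inverse frequency, N1 x 1.5, capped at a 3.5 ratio).

Cross-validation treats whole PSG records — never epochs — as the unit:
k-fold partitions records, leave-one-subject-out (LOSO) holds out all
records of one subject per split, and a simple record-level holdout is
provided for scaled-down experiments.  Metrics are overall accuracy,
Cohen's kappa ((Acc - Pe) / (1 - Pe) with Pe from the confusion
marginals) and one-vs-rest per-class F1, reported from the confusion
matrix pooled over folds (per-fold accuracies are also kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .model import ModelConfig, SleepStagingModel, build_model
from .preprocess import EpochSet
from .stages import ClassWeights, StagingTask, compute_class_weights, \
    map_stage_indices

logger = logging.getLogger("somnastage")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    lr: float = 0.001
    weight_decay: float = 0.001
    amsgrad: bool = True
    lr_step: int = 10
    lr_gamma: float = 0.5
    n_epochs: int = 30
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.weight_decay, self.lr_step, self.lr_gamma,
               self.n_epochs, self.batch_size) <= 0:
            raise ValueError("all training hyperparameters must be positive")


@dataclass(frozen=True)
class FoldSplit:
    """Record-level train/test partitions."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        all_test: list[str] = []
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("train and test records overlap in a fold")
            all_test.extend(test)

    def __len__(self) -> int:
        return len(self.folds)


def make_record_folds(record_ids: Sequence[str], k: int = 5,
                      seed: int = 0) -> FoldSplit:
    """Shuffled partition of records into k near-equal test folds."""
    ids = list(dict.fromkeys(record_ids))  # unique, order-preserving
    if len(ids) < k:
        raise ValueError(f"need at least {k} records for {k} folds, "
                         f"got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    chunks = np.array_split(np.arange(len(perm)), k)
    folds = []
    for c in chunks:
        test = tuple(perm[i] for i in c)
        train = tuple(r for r in perm if r not in set(test))
        folds.append((train, test))
    return FoldSplit(tuple(folds))


def make_loso_splits(record_ids: Sequence[str],
                     subject_ids: Sequence[str] | None = None) -> FoldSplit:
    """One split per subject; the test set is that subject's records.

    ``subject_ids`` maps each record to its subject (parallel sequence);
    without it every record is its own subject.
    """
    ids = list(dict.fromkeys(record_ids))
    if subject_ids is None:
        subject_of = {r: r for r in ids}
    else:
        if len(subject_ids) != len(record_ids):
            raise ValueError("subject_ids must parallel record_ids")
        subject_of = {r: s for r, s in zip(record_ids, subject_ids)}
    subjects = list(dict.fromkeys(subject_of[r] for r in ids))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    folds = []
    for s in subjects:
        test = tuple(r for r in ids if subject_of[r] == s)
        train = tuple(r for r in ids if subject_of[r] != s)
        folds.append((train, test))
    return FoldSplit(tuple(folds))


def make_holdout_split(record_ids: Sequence[str], test_fraction: float = 0.3,
                       seed: int = 0) -> FoldSplit:
    """Single record-level train/test split (for scaled-down experiments)."""
    ids = list(dict.fromkeys(record_ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    if n_test >= len(ids):
        raise ValueError("holdout would leave no training records")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    test = tuple(perm[:n_test])
    train = tuple(perm[n_test:])
    return FoldSplit(((train, test),))


def weighted_cross_entropy(probabilities: np.ndarray,
                           true_labels: np.ndarray,
                           weights: ClassWeights | np.ndarray) -> float:
    """Weighted-mean cross-entropy over samples.

    ``probabilities``: [n, K] rows summing to 1; ``true_labels``: integer
    class indices.  Zero probability at a true label is clamped at 1e-12
    (logged).  loss = sum_i w(y_i) * (-log p_i[y_i]) / sum_i w(y_i).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(true_labels, dtype=np.int64)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    w = weights.weights if isinstance(weights, ClassWeights) \
        else np.asarray(weights, dtype=float)
    py = p[np.arange(len(y)), y]
    if np.any(py <= 0):
        logger.warning("clamping %d zero probabilities at true labels",
                       int(np.sum(py <= 0)))
        py = np.clip(py, 1e-12, None)
    wy = w[y]
    return float(np.sum(wy * -np.log(py)) / np.sum(wy))


def _epochset_tensors(data: EpochSet, task: StagingTask,
                      ) -> tuple[np.ndarray, np.ndarray]:
    x = data.data.astype(np.float32)
    y = map_stage_indices(data.labels, task)
    return x, y


def train_model(model: SleepStagingModel, train_data: EpochSet,
                task: StagingTask, config: TrainConfig,
                class_weights: ClassWeights | None = None,
                ) -> tuple[SleepStagingModel, list[dict]]:
    """Train the staging network; returns the model and a per-epoch trace.

    Class weights default to the capped inverse-frequency weights of the
    *training* labels (mapped to the task's classes).  Deterministic given
    the config seed and the data.
    """
    x, y = _epochset_tensors(train_data, task)
    if class_weights is None:
        counts = {c: int(np.sum(y == i))
                  for i, c in enumerate(task.class_names)}
        class_weights = compute_class_weights(counts)
    logger.info("class weights: %s", class_weights.as_dict())
    sample_w = class_weights.for_labels(y).astype(np.float32)

    opt = nn.Adam(model.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay, amsgrad=config.amsgrad)
    sched = nn.StepLR(opt, step_size=config.lr_step, gamma=config.lr_gamma)
    rng = np.random.default_rng(config.seed)
    model.train()
    trace: list[dict] = []
    n = len(x)
    for epoch in range(config.n_epochs):
        lr_now = opt.lr
        order = rng.permutation(n)
        tot_loss, tot_w, n_correct = 0.0, 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            model.zero_grad()
            logits = model(x[idx])
            loss = nn.weighted_cross_entropy_logits(logits, y[idx],
                                                    sample_w[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at training epoch {epoch}, "
                    f"batch {i // config.batch_size}: lr={lr_now}, "
                    f"check input scaling and learning rate")
            loss.backward()
            opt.step()
            bw = sample_w[idx].sum()
            tot_loss += float(loss.data) * bw
            tot_w += bw
            n_correct += int(np.sum(logits.data.argmax(axis=1) == y[idx]))
        sched.step()
        trace.append({"epoch": epoch, "lr": lr_now,
                      "loss": tot_loss / tot_w,
                      "accuracy": 100.0 * n_correct / n})
        logger.info("epoch %d: lr=%.2e loss=%.4f acc=%.1f%%", epoch, lr_now,
                    trace[-1]["loss"], trace[-1]["accuracy"])
    model.eval()
    return model, trace


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix with overall accuracy, Cohen's kappa and per-class
    precision/recall/F1 (percent)."""

    class_names: tuple[str, ...]
    confusion: np.ndarray           # [K, K] counts, rows = true class

    def __post_init__(self) -> None:
        c = np.asarray(self.confusion, dtype=np.int64)
        if c.shape != (len(self.class_names),) * 2 or np.any(c < 0):
            raise ValueError("confusion must be KxK non-negative counts")
        object.__setattr__(self, "confusion", c)

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        """Overall accuracy in percent: trace / total."""
        return 100.0 * float(np.trace(self.confusion)) / self.n

    @property
    def chance_agreement(self) -> float:
        """Pe: chance agreement probability from the marginals."""
        n = self.n
        rows = self.confusion.sum(axis=1) / n
        cols = self.confusion.sum(axis=0) / n
        return float(np.sum(rows * cols))

    @property
    def kappa(self) -> float:
        """Cohen's kappa, (Acc - Pe) / (1 - Pe)."""
        pe = self.chance_agreement
        if pe >= 1.0:
            return 0.0
        return (self.accuracy / 100.0 - pe) / (1.0 - pe)

    def per_class(self) -> dict[str, dict[str, float]]:
        """One-vs-rest TP/TN/FP/FN, precision, recall and F1 per class."""
        out = {}
        total = self.n
        for i, name in enumerate(self.class_names):
            tp = float(self.confusion[i, i])
            fp = float(self.confusion[:, i].sum() - tp)
            fn = float(self.confusion[i, :].sum() - tp)
            tn = float(total - tp - fp - fn)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            out[name] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
                         "precision": 100.0 * prec, "recall": 100.0 * rec,
                         "f1": 100.0 * f1}
        return out

    @property
    def per_class_f1(self) -> dict[str, float]:
        return {k: v["f1"] for k, v in self.per_class().items()}

    def summary(self) -> dict:
        return {"accuracy": self.accuracy, "kappa": self.kappa,
                "per_class_f1": self.per_class_f1, "n": self.n}


def evaluate(predictions: Sequence, true_labels: Sequence,
             task: StagingTask) -> EvalReport:
    """Confusion matrix and metrics for predicted vs true task labels.

    Labels may be class names or integer class indices.
    """
    def to_idx(seq):
        arr = np.asarray(seq)
        if arr.dtype.kind in "iu":
            return arr.astype(np.int64)
        return np.array([task.class_names.index(str(s)) for s in arr],
                        dtype=np.int64)

    y_pred, y_true = to_idx(predictions), to_idx(true_labels)
    if len(y_pred) != len(y_true):
        raise ValueError("predictions and labels differ in length")
    if len(y_true) == 0:
        raise ValueError("cannot evaluate on empty input")
    k = task.n_classes
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (y_true, y_pred), 1)
    return EvalReport(task.class_names, conf)


def export_hypnogram(true_labels: Sequence, predicted_labels: Sequence,
                     record_id: str, csv_path, plot_path=None) -> int:
    """Aligned per-epoch true/predicted comparison; returns mismatch count.

    Writes a CSV (epoch_index, true, predicted, match) and optionally a
    stepped-line hypnogram plot.
    """
    t = [str(s) for s in true_labels]
    p = [str(s) for s in predicted_labels]
    if len(t) != len(p):
        raise ValueError("true and predicted sequences differ in length")
    mismatches = sum(a != b for a, b in zip(t, p))
    with open(csv_path, "w") as fh:
        fh.write("epoch_index,true,predicted,match\n")
        for i, (a, b) in enumerate(zip(t, p)):
            fh.write(f"{i},{a},{b},{int(a == b)}\n")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = list(dict.fromkeys(t + p))
        lut = {s: i for i, s in enumerate(order)}
        fig, axes = plt.subplots(2, 1, sharex=True, figsize=(10, 4))
        for ax, seq, title in zip(axes, (t, p),
                                  (f"{record_id}: expert", "predicted")):
            ax.step(range(len(seq)), [lut[s] for s in seq], where="post")
            ax.set_yticks(range(len(order)), order)
            ax.set_title(title, fontsize=9)
        axes[1].set_xlabel("epoch (30 s)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=110)
        plt.close(fig)
    return mismatches


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

def _split_for(protocol: str, record_ids, seed: int, k: int,
               subjects=None, test_fraction: float = 0.3) -> FoldSplit:
    if protocol == "cv5":
        return make_record_folds(record_ids, k=k, seed=seed)
    if protocol == "loso":
        return make_loso_splits(record_ids, subjects)
    if protocol == "holdout":
        return make_holdout_split(record_ids, test_fraction, seed)
    raise ValueError(f"unknown protocol {protocol!r}")


def run_protocol(data: EpochSet, task: StagingTask, split: FoldSplit,
                 model_config: ModelConfig, train_config: TrainConfig,
                 ) -> tuple[EvalReport, list[dict]]:
    """Train/evaluate over the folds of a split; pooled confusion matrix.

    Asserts per fold that no test-record epoch is seen in training.
    """
    conf = np.zeros((task.n_classes,) * 2, dtype=np.int64)
    fold_rows = []
    for f, (train_ids, test_ids) in enumerate(split.folds):
        train_mask = np.isin(data.record_ids, train_ids)
        test_mask = np.isin(data.record_ids, test_ids)
        assert not np.any(train_mask & test_mask), "record leakage in fold"
        train_set, test_set = data.subset(train_mask), data.subset(test_mask)
        model = build_model(model_config)
        model, _ = train_model(model, train_set, task, train_config)
        x_test, y_test = _epochset_tensors(test_set, task)
        pred = model.predict(x_test)
        rep = evaluate(pred, y_test, task)
        conf += rep.confusion
        fold_rows.append({"fold": f, "n_test": len(y_test),
                          "accuracy": rep.accuracy, "kappa": rep.kappa})
        logger.info("fold %d: acc=%.2f%% kappa=%.3f (n=%d)", f,
                    rep.accuracy, rep.kappa, len(y_test))
    return EvalReport(task.class_names, conf), fold_rows


def run_comparison(channel_configs: Mapping[str, Sequence[str]],
                   task: StagingTask, data: EpochSet,
                   protocol: str = "cv5",
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   seed: int = 0, k: int = 5, subjects=None,
                   test_fraction: float = 0.3):
    """Compare channel configurations under identical fold assignments.

    ``channel_configs`` maps a configuration name (e.g. ``"EEG+2xEOG"``)
    to the channel names it uses.  Every configuration is trained and
    evaluated on the *same* record folds (paired design); metrics come
    from the confusion matrix pooled over folds.  Returns a DataFrame
    sorted by pooled accuracy plus the per-config EvalReports.
    """
    import pandas as pd

    train_config = train_config or TrainConfig()
    base_model_config = model_config or ModelConfig(n_classes=task.n_classes)
    split = _split_for(protocol, data.record_ids, seed, k, subjects,
                       test_fraction)
    rows, reports = [], {}
    for name, channels in channel_configs.items():
        missing = [c for c in channels if c not in data.channel_names]
        if missing:
            logger.warning("skipping config %s: missing channels %s",
                           name, missing)
            continue
        sub = data.select_channels(list(channels))
        import dataclasses as _dc
        mc = _dc.replace(base_model_config, n_channels=len(channels),
                         n_classes=task.n_classes, seed=seed)
        report, fold_rows = run_protocol(sub, task, split, mc, train_config)
        reports[name] = report
        fold_accs = [r["accuracy"] for r in fold_rows]
        rows.append({
            "config": name, "channels": "+".join(channels),
            "n_channels": len(channels),
            "accuracy": report.accuracy,
            "accuracy_fold_mean": float(np.mean(fold_accs)),
            "kappa": report.kappa,
            **{f"f1_{c}": v for c, v in report.per_class_f1.items()},
        })
    table = pd.DataFrame(rows).sort_values(
        "accuracy", ascending=False).reset_index(drop=True)
    return table, reports
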