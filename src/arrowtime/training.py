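"""Pretext-task construction, supervised training, cross-validation and transfer.

The core pretext task is time reversal (TR): every subject contributes its
original matrix with label 0 and its time-reversed copy with label 1, and the
classifier learns to tell the arrow of time. Two contrastive baselines are
provided for comparison — order-contrastive pretraining (OCP: segment pairs,
half deliberately misordered) and permutation contrastive learning (PCL:
adjacent-window positives, random same-trajectory window-pair negatives).

Training uses Adam with a reduce-on-plateau learning-rate schedule, a
stratified validation split, early stopping on validation loss, and returns
the best-validation parameters. Everything is deterministic given the
config seeds (single-threaded BLAS assumed for bitwise repeatability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core_data import Cohort, LabeledSequence
from .model import ModelConfig, SequenceClassifier, init_model

__all__ = [
    "TrainConfig",
    "FoldMetrics",
    "PairExample",
    "reverse_time",
    "build_tr_dataset",
    "bce_loss",
    "train",
    "auc",
    "accuracy",
    "balanced_accuracy",
    "cross_validate",
    "transfer_weights",
    "build_ocp_pairs",
    "build_pcl_pairs",
    "pretrain",
]

_BCE_EPS = 1e-7


@dataclass
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults: Adam at learning rate 7e-4, batch size 32, up to 1000 epochs
    with early stopping (patience 20 epochs on validation loss), and a
    plateau scheduler halving the learning rate after 10 stagnant epochs.
    """

    learning_rate: float = 7e-4
    batch_size: int = 32
    max_epochs: int = 1000
    early_stop_patience: int = 20
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    min_lr: float = 1e-6
    n_folds: int = 10
    val_fraction: float = 0.2
    grad_clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class FoldMetrics:
    """Held-out metrics for one cross-validation fold."""

    fold_index: int
    auc: float
    accuracy: float
    balanced_accuracy: float
    train_curve: list[float] = field(default_factory=list)
    val_curve: list[float] = field(default_factory=list)


@dataclass
class PairExample:
    """A pair of equal-length segments from one trajectory with an order label."""

    segment_a: np.ndarray
    segment_b: np.ndarray
    y: int
    origin_id: str

    def __post_init__(self) -> None:
        if self.segment_a.shape != self.segment_b.shape:
            raise ValueError("segments must have equal shape")
        if self.y not in (0, 1):
            raise ValueError("y must be 0 or 1")

    def as_sequence(self) -> LabeledSequence:
        """Present the pair as one 2L x N sequence (time-axis concatenation)."""
        return LabeledSequence(
            np.concatenate([self.segment_a, self.segment_b], axis=0), self.y, self.origin_id
        )


# ---------------------------------------------------------------- datasets


def reverse_time(X: np.ndarray) -> np.ndarray:
    """Reverse the time axis: output row t equals input row T-t-1."""
    X = np.asarray(X)
    return X[::-1].copy()


def build_tr_dataset(cohort: Cohort) -> list[LabeledSequence]:
    """Balanced forward/reversed dataset: (X, 0) and (reverse_time(X), 1) per subject."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    out: list[LabeledSequence] = []
    for s in cohort:
        out.append(LabeledSequence(s.values.copy(), 0, s.subject_id))
        out.append(LabeledSequence(reverse_time(s.values), 1, s.subject_id))
    return out


def build_ocp_pairs(
    cohort: Cohort, segment_len: int, pairs_per_subject: int, seed: int
) -> list[PairExample]:
    """Order-contrastive pairs: non-overlapping segments, first-before-second.

    Per subject, half the pairs (rounded down) are presented order-switched
    with y=0 (negatives); the rest keep temporal order with y=1.
    """
    T = cohort.n_timepoints
    if 2 * segment_len > T:
        raise ValueError(f"segment_len {segment_len} too large for T={T}")
    rng = np.random.default_rng(seed)
    out: list[PairExample] = []
    for s in cohort:
        n_neg = pairs_per_subject // 2
        for k in range(pairs_per_subject):
            start_a = int(rng.integers(0, T - 2 * segment_len + 1))
            start_b = int(rng.integers(start_a + segment_len, T - segment_len + 1))
            seg_a = s.values[start_a : start_a + segment_len].copy()
            seg_b = s.values[start_b : start_b + segment_len].copy()
            if k < n_neg:  # misordered negative
                out.append(PairExample(seg_b, seg_a, 0, s.subject_id))
            else:
                out.append(PairExample(seg_a, seg_b, 1, s.subject_id))
    return out


def build_pcl_pairs(
    cohort: Cohort, window_len: int, pairs_per_subject: int, seed: int
) -> list[PairExample]:
    """Permutation-contrastive pairs: adjacent-window positives, random negatives.

    Positives are consecutive windows (start_b = start_a + window_len), y=1.
    Negatives are two windows drawn uniformly from the same trajectory with
    distinct starts and no order constraint — they may be correctly ordered.
    """
    T = cohort.n_timepoints
    if 2 * window_len > T:
        raise ValueError(f"window_len {window_len} too large for T={T}")
    rng = np.random.default_rng(seed)
    out: list[PairExample] = []
    for s in cohort:
        n_neg = pairs_per_subject // 2
        for k in range(pairs_per_subject):
            if k < n_neg:
                start_a = int(rng.integers(0, T - window_len + 1))
                start_b = start_a
                while start_b == start_a:
                    start_b = int(rng.integers(0, T - window_len + 1))
                y = 0
            else:
                start_a = int(rng.integers(0, T - 2 * window_len + 1))
                start_b = start_a + window_len
                y = 1
            out.append(
                PairExample(
                    s.values[start_a : start_a + window_len].copy(),
                    s.values[start_b : start_b + window_len].copy(),
                    y,
                    s.subject_id,
                )
            )
    return out


# ------------------------------------------------------------------- loss


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clamped to [eps, 1-eps], eps=1e-7."""
    y = np.asarray(y, dtype=float)
    y_hat = np.clip(np.asarray(y_hat, dtype=float), _BCE_EPS, 1.0 - _BCE_EPS)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    return float(-np.mean(y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat)))


# ---------------------------------------------------------------- metrics


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank-statistic (Mann-Whitney) formula.

    Midranks handle ties; requires both classes present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def accuracy(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> float:
    labels = np.asarray(labels, dtype=int)
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    return float(np.mean(pred == labels))


def balanced_accuracy(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> float:
    """Mean of per-class recalls at the given probability threshold."""
    labels = np.asarray(labels, dtype=int)
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    recalls = [np.mean(pred[labels == c] == c) for c in (0, 1) if np.any(labels == c)]
    return float(np.mean(recalls))


# --------------------------------------------------------------- training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    if max_norm <= 0:
        return
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _stack(data: Sequence[LabeledSequence]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([d.values for d in data])
    y = np.array([d.y for d in data], dtype=float)
    return X, y


def train(
    model: SequenceClassifier,
    data: Sequence[LabeledSequence],
    config: TrainConfig,
) -> tuple[SequenceClassifier, dict]:
    """Train on labeled sequences; returns (best-validation model, history).

    A stratified ``val_fraction`` split is carved from ``data``; Adam drives
    the updates, validation loss drives the plateau scheduler and early
    stopping, and the parameters with the best validation loss are returned.
    Fully deterministic given ``config.seed``.
    """
    if len(data) == 0:
        raise ValueError("no training data")
    X, y = _stack(data)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    idx_train, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=config.val_fraction,
        random_state=config.seed,
        stratify=y,
    )
    Xtr, ytr = X[idx_train], y[idx_train]
    Xval, yval = X[idx_val], y[idx_val]

    rng = np.random.default_rng(config.seed)
    model = model.copy()
    opt = _Adam(model.parameters, config.learning_rate)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.parameters.items()}
    bad_epochs = 0
    lr_bad_epochs = 0
    history: dict = {"train_curve": [], "val_curve": [], "lr": [], "train_acc": []}

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(ytr))
        epoch_losses = []
        n_correct = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = Xtr[batch], ytr[batch]
            probs, cache = model.forward_batch(xb, training=True, dropout_rng=rng)
            epoch_losses.append(bce_loss(yb, probs) * len(batch))
            n_correct += int(np.sum((probs > 0.5) == (yb > 0.5)))
            dlogit = (probs - yb) / len(batch)
            grads, _ = model.backward_batch(cache, dlogit)
            _clip_grads(grads, config.grad_clip_norm)
            opt.step(model.parameters, grads)
        train_loss = float(np.sum(epoch_losses) / len(ytr))
        val_probs = model.predict_proba(Xval)
        val_loss = bce_loss(yval, val_probs)
        history["train_curve"].append(train_loss)
        history["val_curve"].append(val_loss)
        history["train_acc"].append(n_correct / len(ytr))
        history["lr"].append(opt.lr)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.parameters.items()}
            bad_epochs = 0
            lr_bad_epochs = 0
        else:
            bad_epochs += 1
            lr_bad_epochs += 1
            if lr_bad_epochs > config.scheduler_patience:
                opt.lr = max(opt.lr * config.scheduler_factor, config.min_lr)
                lr_bad_epochs = 0
            if bad_epochs > config.early_stop_patience:
                break

    best_model = SequenceClassifier(model.config, best_params, model.provenance)
    history["stopped_epoch"] = epoch
    history["best_val_loss"] = best_val
    return best_model, history


# ------------------------------------------------------ CV and transfer


def transfer_weights(
    donor: SequenceClassifier,
    target_config: ModelConfig,
    reinit_head: bool = False,
    donor_tag: str = "donor",
) -> SequenceClassifier:
    """Copy donor parameters into a model of structurally identical config.

    With ``reinit_head=True`` the decoder layers are re-drawn Xavier-normal
    under ``target_config.seed``; encoder and attention always transfer.
    """
    dc, tc = donor.config, target_config
    structural = ("input_size", "lstm_hidden", "lstm_layers", "attention_hidden",
                  "decoder_hidden", "use_attention", "encoder_kind")
    for f in structural:
        if getattr(dc, f) != getattr(tc, f):
            raise ValueError(f"config mismatch on {f!r}: donor={getattr(dc, f)} target={getattr(tc, f)}")
    params = {k: v.copy() for k, v in donor.parameters.items()}
    if reinit_head:
        fresh = init_model(target_config)
        for k in list(params):
            if k.startswith("dec."):
                params[k] = fresh.parameters[k]
    return SequenceClassifier(target_config, params, provenance=f"pretrained:{donor_tag}")


def cross_validate(
    cohort: Cohort,
    model_config: ModelConfig,
    train_config: TrainConfig,
    init_from: Optional[SequenceClassifier] = None,
    reinit_head: bool = False,
) -> list[FoldMetrics]:
    """Stratified k-fold evaluation of the downstream classifier.

    Each fold trains a fresh model (or a copy of ``init_from``'s weights)
    on the remaining folds and reports held-out AUC, accuracy and balanced
    accuracy. Folds are stratified by label; every subject appears in
    exactly one test fold.
    """
    labels = cohort.labels
    if labels is None:
        raise ValueError("cross_validate requires a fully labeled cohort")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < train_config.n_folds:
        raise ValueError(
            f"n_folds={train_config.n_folds} exceeds minority class size {counts.min()}"
        )
    X = np.stack([s.values for s in cohort])
    skf = StratifiedKFold(
        n_splits=train_config.n_folds, shuffle=True, random_state=train_config.seed
    )
    results: list[FoldMetrics] = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(X, labels)):
        fold_model_cfg = ModelConfig(**{**model_config.__dict__, "seed": model_config.seed + fold})
        if init_from is not None:
            m0 = transfer_weights(init_from, fold_model_cfg, reinit_head=reinit_head,
                                  donor_tag=init_from.provenance)
        else:
            m0 = init_model(fold_model_cfg)
        fold_train_cfg = TrainConfig(**{**train_config.__dict__, "seed": train_config.seed + fold})
        data = [
            LabeledSequence(X[i], int(labels[i]), cohort.subjects[i].subject_id) for i in tr_idx
        ]
        fitted, hist = train(m0, data, fold_train_cfg)
        scores = fitted.predict_proba(X[te_idx])
        results.append(
            FoldMetrics(
                fold_index=fold,
                auc=auc(labels[te_idx], scores),
                accuracy=accuracy(labels[te_idx], scores),
                balanced_accuracy=balanced_accuracy(labels[te_idx], scores),
                train_curve=hist["train_curve"],
                val_curve=hist["val_curve"],
            )
        )
    return results


# ------------------------------------------------------------- pretraining


def pretrain(
    method: str,
    cohort: Cohort,
    model_config: ModelConfig,
    train_config: TrainConfig,
    test_fraction: float = 0.2,
    segment_len: Optional[int] = None,
    pairs_per_subject: int = 4,
) -> tuple[SequenceClassifier, float]:
    """Self-supervised pretraining; returns (model, held-out accuracy).

    ``method`` is one of ``tr`` (forward vs. time-reversed), ``ocp``
    (ordered vs. misordered segment pairs) or ``pcl`` (adjacent vs. random
    window pairs). Pair methods present each pair as the time-axis
    concatenation of its two segments. The held-out split is carved at the
    example level, stratified by label.
    """
    if method not in ("tr", "ocp", "pcl"):
        raise ValueError(f"unknown pretraining method {method!r}")
    if method == "tr":
        examples = build_tr_dataset(cohort)
    else:
        if segment_len is None:
            segment_len = cohort.n_timepoints // 4
        builder = build_ocp_pairs if method == "ocp" else build_pcl_pairs
        pairs = builder(cohort, segment_len, pairs_per_subject, train_config.seed)
        examples = [p.as_sequence() for p in pairs]
    y = np.array([e.y for e in examples])
    idx_train, idx_test = train_test_split(
        np.arange(len(examples)),
        test_size=test_fraction,
        random_state=train_config.seed,
        stratify=y,
    )
    train_examples = [examples[i] for i in idx_train]
    test_examples = [examples[i] for i in idx_test]
    model0 = init_model(model_config)
    fitted, _ = train(model0, train_examples, train_config)
    Xte, yte = _stack(test_examples)
    test_acc = accuracy(yte, fitted.predict_proba(Xte))
    return fitted, test_acc
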