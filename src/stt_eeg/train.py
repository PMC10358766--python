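"""Composite-loss training, k-fold evaluation and ablation sweeps.

The objective is the weighted cross-entropy composite

    loss = alpha * CE(y_spatial) + (1 - alpha) * CE(y_temporal)
           + fused_loss_weight * CE(y_fused)

with alpha = 0.3 by default.  The fused-head term (unit weight by
default) trains the fusion layer whose output drives the reported
classification; set ``fused_loss_weight = 0`` to optimize the two-stream
composite alone.  Optimization uses the AMSGrad variant of Adam at
learning rate 0.001.

Evaluation reports sensitivity TP/(TP+FN), specificity TN/(TN+FP) and
accuracy (TP+TN)/N, per fold of a label-stratified k-fold split and
averaged over folds; with three classes the counts are one-vs-rest and
sensitivity/specificity are macro-averaged.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import autograd as ag
from .autograd import Tensor
from .eeg_io import EpochGroup
from .errors import ConfigError, DataError, TrainingError
from .model import ModelConfig, SttModel, SttOutputs, _slab_stack

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "ConfusionCounts", "EvalReport", "AMSGrad",
    "composite_loss", "compute_metrics", "confusion_counts", "kfold_split",
    "train_model", "evaluate", "run_cv", "ablation_channels", "ablation_grid",
]

VARIANTS = ("combined", "spatial", "temporal")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (AMSGrad, lr 0.001 per the protocol)."""

    lr: float = 1e-3
    max_epochs: int = 25
    batch_size: int = 24
    fused_loss_weight: float = 1.0
    val_fraction: float = 0.0  # > 0 enables best-validation checkpointing
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ConfigError("learning rate must be positive")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ConfigError("max_epochs and batch_size must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ConfigError("val_fraction must be in [0, 1)")


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    TP: int = 0
    FN: int = 0
    TN: int = 0
    FP: int = 0

    @property
    def n(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


def _metric(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning,
                      stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts.

    Zero-denominator metrics are reported as NaN with a warning, never 0.
    """
    if counts.n == 0:
        raise DataError("no evaluated samples")
    sens = _metric(counts.TP, counts.TP + counts.FN, "sensitivity")
    spec = _metric(counts.TN, counts.TN + counts.FP, "specificity")
    acc = _metric(counts.TP + counts.TN, counts.n, "accuracy")
    return sens, spec, acc


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> list[ConfusionCounts]:
    """Per-class one-vs-rest counts from integer class indices."""
    out = []
    for c in range(n_classes):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        tn = int(np.sum((y_true != c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        out.append(ConfusionCounts(tp, fn, tn, fp))
    return out


def macro_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                  n_classes: int) -> tuple[float, float, float]:
    """Macro one-vs-rest sensitivity/specificity; overall accuracy.

    For two classes this reduces to the plain single-positive-class
    definition with class 1 treated as positive.
    """
    if n_classes == 2:
        counts = confusion_counts(y_true, y_pred, 2)[1]
        return compute_metrics(counts)
    per = [compute_metrics(c) for c in confusion_counts(y_true, y_pred, n_classes)]
    sens = float(np.mean([m[0] for m in per]))
    spec = float(np.mean([m[1] for m in per]))
    acc = float(np.mean(y_true == y_pred))
    return sens, spec, acc


# ---------------------------------------------------------------------------
# Loss and optimizer

def composite_loss(outs: SttOutputs, labels: np.ndarray, alpha: float,
                   fused_loss_weight: float = 1.0) -> Tensor:
    """alpha-weighted two-stream cross entropy plus the fused-head term."""
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"alpha must be in [0, 1], got {alpha}")
    labels = np.asarray(labels)
    loss = (np.float32(alpha) * ag.cross_entropy_logits(outs.y_spatial, labels)
            + np.float32(1.0 - alpha) * ag.cross_entropy_logits(outs.y_temporal, labels))
    if fused_loss_weight > 0.0:
        loss = loss + np.float32(fused_loss_weight) * ag.cross_entropy_logits(
            outs.y, labels)
    return loss


class AMSGrad:
    """Adam with a non-decreasing second-moment maximum (AMSGrad)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.vhat = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            np.maximum(self.vhat[k], self.v[k], out=self.vhat[k])
            mhat = self.m[k] / bc1
            vhat = self.vhat[k] / bc2
            p.data = p.data - np.float32(self.lr) * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Data plumbing

def label_to_index(labels: Iterable[int]) -> tuple[np.ndarray, list[int]]:
    """Map emotion labels in {-1, 0, +1} to contiguous class indices."""
    labels = list(labels)
    classes = sorted(set(labels))
    lut = {lab: i for i, lab in enumerate(classes)}
    return np.array([lut[l] for l in labels], dtype=np.int64), classes


def groups_to_batch(groups: Sequence[EpochGroup]) -> np.ndarray:
    return np.stack([g.as_array() for g in groups]).astype(np.float32)


def kfold_split(groups: Sequence[EpochGroup], k: int = 10, seed: int = 0,
                subject_wise: bool = False) -> list[tuple[list[int], list[int]]]:
    """Label-stratified k-fold partition of group indices.

    Fold sizes differ by at most one and every group is tested exactly
    once.  ``subject_wise=True`` instead assigns whole subjects to folds
    (round-robin over a seed-shuffled subject list), avoiding leakage
    between overlapped epochs of one subject across train and test.
    """
    n = len(groups)
    if k < 2 or k > n:
        raise DataError(f"k={k} must be in [2, n_groups={n}]")
    y, _ = label_to_index(g.label for g in groups)
    if subject_wise:
        subjects = sorted({g.subject_id for g in groups})
        if k > len(subjects):
            raise DataError(f"k={k} exceeds {len(subjects)} subjects")
        rng = np.random.default_rng(seed)
        rng.shuffle(subjects)
        fold_of = {s: i % k for i, s in enumerate(subjects)}
        assign = np.array([fold_of[g.subject_id] for g in groups])
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        assign = np.empty(n, dtype=int)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), y)):
            assign[test_idx] = fold
    splits = []
    for fold in range(k):
        test = np.flatnonzero(assign == fold)
        train = np.flatnonzero(assign != fold)
        splits.append((train.tolist(), test.tolist()))
    return splits


# ---------------------------------------------------------------------------
# Training / evaluation

def train_model(model: SttModel, batch: np.ndarray, y: np.ndarray,
                train_cfg: TrainConfig, alpha: float | None = None) -> list[float]:
    """Minibatch AMSGrad training on a fixed-epoch budget.

    Returns the per-epoch mean loss.  With ``val_fraction > 0`` a held-out
    slice of the training set scores the model after every epoch and the
    best-scoring parameters are restored at the end (best-validation
    checkpointing; there is no early stopping).
    """
    alpha = model.cfg.alpha if alpha is None else alpha
    opt = AMSGrad(model.params, lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed)
    slabs = _slab_stack(batch.astype(np.float32), model.cfg)  # tokenize once
    n = batch.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(train_cfg.val_fraction * n))
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    best_acc, best_params = -1.0, None
    history = []
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(fit_idx))
        losses = []
        for start in range(0, len(fit_idx), train_cfg.batch_size):
            idx = fit_idx[order[start:start + train_cfg.batch_size]]
            model.zero_grad()
            outs = model.forward_slabs(slabs[idx], train=True)
            loss = composite_loss(outs, y[idx], alpha,
                                  train_cfg.fused_loss_weight)
            if not np.isfinite(loss.data):
                raise TrainingError(f"divergent loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if n_val:
            outs = model.forward_slabs(slabs[val_idx], train=False)
            acc = float(np.mean(np.argmax(outs.y.data, axis=-1) == y[val_idx]))
            if acc > best_acc:
                best_acc = acc
                best_params = {k: p.data.copy() for k, p in model.params.items()}
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    return history


def evaluate(model: SttModel, batch: np.ndarray,
             eval_batch_size: int = 64) -> dict[str, np.ndarray]:
    """Argmax predictions of each logit set on a batch of groups."""
    preds = {v: [] for v in VARIANTS}
    slabs = _slab_stack(batch.astype(np.float32), model.cfg)
    for start in range(0, batch.shape[0], eval_batch_size):
        outs = model.forward_slabs(slabs[start:start + eval_batch_size],
                                   train=False)
        for v in VARIANTS:
            preds[v].append(np.argmax(outs.logits(v).data, axis=-1))
    return {v: np.concatenate(p) for v, p in preds.items()}


@dataclass
class EvalReport:
    """Per-fold and aggregate metrics of one cross-validated run."""

    per_fold: list[dict]          # fold -> {variant: [sens, spec, acc]}
    aggregate: dict               # variant -> [sens, spec, acc] (fold mean)
    per_class: dict               # variant -> per-class metric triples
    variant: str                  # variant whose loss drove training
    model_config: dict
    train_config: dict
    k: int = 10

    def accuracy(self, variant: str | None = None) -> float:
        return self.aggregate[variant or self.variant][2]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _variant_weights(variant: str, alpha: float,
                     fused: float) -> tuple[float, float]:
    """(alpha, fused_loss_weight) realizing a channel-ablation variant."""
    if variant == "combined":
        return alpha, fused
    if variant == "spatial":
        return 1.0, 0.0
    if variant == "temporal":
        return 0.0, 0.0
    raise ConfigError(f"unknown variant {variant!r}")


def run_cv(groups: Sequence[EpochGroup], model_cfg: ModelConfig,
           train_cfg: TrainConfig, k: int = 10, variant: str = "combined",
           subject_wise: bool = False, split_seed: int | None = None) -> EvalReport:
    """Train a fresh model per fold and evaluate on the held-out fold.

    The reported headline metrics use the logits matching ``variant``
    (fused ``y`` for "combined"); spatial-only and temporal-only metrics
    are recorded alongside for the channel ablation.
    """
    labels = [g.label for g in groups]
    y, classes = label_to_index(labels)
    n_classes = len(classes)
    if n_classes != model_cfg.n_classes:
        model_cfg = replace(model_cfg, n_classes=n_classes)
    per_label = min(np.bincount(y))
    if per_label < k:
        raise DataError(f"only {per_label} groups in the rarest class; k={k}")
    split_seed = train_cfg.seed if split_seed is None else split_seed
    splits = kfold_split(groups, k=k, seed=split_seed, subject_wise=subject_wise)
    batch_all = groups_to_batch(groups)
    alpha_v, fused_v = _variant_weights(
        variant, model_cfg.alpha, train_cfg.fused_loss_weight)
    fold_rows: list[dict] = []
    class_acc: dict[str, list] = {v: [] for v in VARIANTS}
    preds_all = {v: np.empty(len(groups), dtype=np.int64) for v in VARIANTS}
    for fold, (train_idx, test_idx) in enumerate(splits):
        fold_seed = (train_cfg.seed * 1009 + fold) % (2 ** 31)
        model = SttModel(replace(model_cfg, seed=fold_seed))
        fold_tc = replace(train_cfg, seed=fold_seed,
                          fused_loss_weight=fused_v)
        hist = train_model(model, batch_all[train_idx], y[train_idx],
                           fold_tc, alpha=alpha_v)
        preds = evaluate(model, batch_all[test_idx])
        row = {}
        for v in VARIANTS:
            row[v] = list(macro_metrics(y[test_idx], preds[v], n_classes))
            preds_all[v][test_idx] = preds[v]
        fold_rows.append(row)
        logger.info("fold %d/%d: loss %.4f -> %.4f, acc(%s)=%.3f",
                    fold + 1, k, hist[0], hist[-1], variant, row[variant][2])
    aggregate = {
        v: list(np.mean([r[v] for r in fold_rows], axis=0)) for v in VARIANTS
    }
    per_class = {
        v: [list(compute_metrics(c))
            for c in confusion_counts(y, preds_all[v], n_classes)]
        for v in VARIANTS
    }
    return EvalReport(
        per_fold=fold_rows, aggregate=aggregate, per_class=per_class,
        variant=variant, model_config=asdict(model_cfg),
        train_config=asdict(train_cfg), k=k,
    )


def ablation_channels(groups: Sequence[EpochGroup], model_cfg: ModelConfig,
                      train_cfg: TrainConfig, k: int = 10,
                      subject_wise: bool = False) -> pd.DataFrame:
    """Spatial-only vs temporal-only vs combined, on shared data splits."""
    rows = []
    for variant in VARIANTS:
        rep = run_cv(groups, model_cfg, train_cfg, k=k, variant=variant,
                     subject_wise=subject_wise, split_seed=train_cfg.seed)
        sens, spec, acc = rep.aggregate[variant]
        rows.append({"variant": variant, "sensitivity": sens,
                     "specificity": spec, "accuracy": acc})
    return pd.DataFrame(rows)


def ablation_grid(groups: Sequence[EpochGroup], heads_set: Sequence[int],
                  layers_set: Sequence[int], model_cfg: ModelConfig,
                  train_cfg: TrainConfig, k: int = 10,
                  done: pd.DataFrame | None = None) -> pd.DataFrame:
    """Heads x layers accuracy sweep with shared splits and seeds.

    ``done`` (a previous partial result table) lets an interrupted sweep
    resume: cells already present are copied, not recomputed.
    """
    cache = {}
    if done is not None and len(done):
        cache = {(int(r.n_heads), int(r.n_layers)): r for r in done.itertuples()}
    rows = []
    for h in heads_set:
        for l in layers_set:
            if (h, l) in cache:
                r = cache[(h, l)]
                rows.append({"model": r.model, "n_heads": h, "n_layers": l,
                             "accuracy": float(r.accuracy)})
                continue
            cfg = replace(model_cfg, n_heads=h, L=l)
            rep = run_cv(groups, cfg, train_cfg, k=k,
                         split_seed=train_cfg.seed)
            rows.append({"model": f"STT_{h}_{l}", "n_heads": h,
                         "n_layers": l, "accuracy": rep.accuracy()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plots (SVG)

def plot_alpha_curve(alphas: Sequence[float], accuracies: Sequence[float],
                     path: str | Path) -> None:
    """Accuracy vs loss-weight alpha, as an SVG line plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(alphas, accuracies, "o-")
    ax.set_xlabel(r"spatial loss weight $\alpha$")
    ax.set_ylabel("accuracy")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_channel_ablation(table: pd.DataFrame, path: str | Path) -> None:
    """Grouped bar chart of the three channel-ablation variants."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["sensitivity", "specificity", "accuracy"]
    x = np.arange(len(metrics))
    width = 0.25
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    for i, row in table.iterrows():
        ax.bar(x + (i - 1) * width, [row[m] for m in metrics], width,
               label=row["variant"])
    ax.set_xticks(x, metrics)
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
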