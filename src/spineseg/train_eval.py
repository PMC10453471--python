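"""Dataset splitting, loss, training loop and evaluation.

The loss is an equally weighted sum of (1 - soft dice) and per-voxel
cross-entropy; the optimizer is the adaptive-moment method at the configured
initial rate with reduce-on-plateau decay (factor 0.5, patience 10 epochs on
the validation macro dice).  Splits are made at volume granularity so slices
of one scan can never leak between train and test.  With fixed seeds and
single-threaded execution the whole train -> evaluate path is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import metrics, nn
from .nn import Tensor


@dataclass
class TrainConfig:
    epochs: int = 150
    lr: float = 0.001
    batch_size: int = 8
    dropout: float = 0.3
    loss_weights: tuple[float, float] = (0.5, 0.5)  # (dice term, CE term)
    seed: int = 0
    split_fraction: float = 0.8
    plateau_factor: float = 0.5
    plateau_patience: int = 10

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must lie in (0, 1)")
        if self.lr <= 0 or self.epochs < 1:
            raise ValueError("lr must be > 0 and epochs >= 1")


def split_dataset(items: Sequence, fraction: float = 0.8,
                  seed: int = 0) -> tuple[list, list]:
    """Deterministic shuffled split: round(n*fraction) train, rest test."""
    if len(items) < 2:
        raise ValueError("need at least 2 items to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    idx = np.random.default_rng(seed).permutation(len(items))
    n_train = int(round(len(items) * fraction))
    n_train = min(max(n_train, 1), len(items) - 1)
    train = [items[i] for i in sorted(idx[:n_train])]
    test = [items[i] for i in sorted(idx[n_train:])]
    return train, test


def soft_dice(probs: Tensor, truth_idx: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Differentiable mean soft dice over classes; 1.0 at a perfect one-hot fit.

    probs: (N, C, ...) softmax output; truth_idx: (N, ...) integer labels.
    """
    n_classes = probs.shape[1]
    onehot = np.zeros(probs.shape, dtype=np.float32)
    np.put_along_axis(onehot, np.expand_dims(truth_idx, 1), 1.0, axis=1)
    axes = (0,) + tuple(range(2, probs.ndim))
    inter = (probs * onehot).sum(axis=axes)
    totals = probs.sum(axis=axes) + Tensor(onehot.sum(axis=axes))
    dice_c = (2.0 * inter + smooth) / (totals + smooth)
    return dice_c.mean()


def segmentation_loss(logits: Tensor, truth_idx: np.ndarray,
                      weights: tuple[float, float] = (0.5, 0.5)) -> Tensor:
    """weights[0]*(1 - soft dice) + weights[1]*cross-entropy."""
    if logits.shape[0] != np.asarray(truth_idx).shape[0] or \
            logits.shape[2:] != np.asarray(truth_idx).shape[1:]:
        raise ValueError(
            f"logits {logits.shape} and truth {np.shape(truth_idx)} misaligned")
    w_dice, w_ce = weights
    probs = nn.softmax(logits, axis=1)
    loss = w_dice * (1.0 - soft_dice(probs, truth_idx))
    loss = loss + w_ce * nn.cross_entropy(logits, truth_idx, axis=1)
    return loss


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_dice: float
    lr: float


def macro_dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Macro dice over classes present in the truth; binary dice when the
    truth holds no foreground class (background-only samples)."""
    if not (np.asarray(truth) > 0).any():
        return metrics.dice(np.asarray(pred) > 0, np.asarray(truth) > 0)
    return metrics.macro_report(pred, truth)["macro"]["dice"]


def binary_dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    return metrics.dice(np.asarray(pred) > 0, np.asarray(truth) > 0)


def _val_score(predict: Callable, val_items: Sequence,
               score: Callable) -> float:
    return float(np.mean([score(predict(x), t) for x, t in val_items]))


def train(model: nn.Module, train_items: Sequence, val_items: Sequence,
          cfg: TrainConfig, forward: Callable[[nn.Module, np.ndarray], Tensor],
          predict: Callable[[np.ndarray], np.ndarray],
          augment_fn: Callable | None = None,
          score: Callable[[np.ndarray, np.ndarray], float] = macro_dice_score,
          log: Callable[[str], None] | None = None
          ) -> tuple[list[EpochRecord], dict]:
    """Generic seeded training loop over (input, integer-target) pairs.

    `forward` maps (model, batch input) to logits; `predict` maps one input
    to an integer label array for validation scoring; `augment_fn(x, t, rng)`
    is applied on the fly to each training pair.  Returns the per-epoch
    history and the best-validation-dice state dict.
    """
    if not len(train_items) or not len(val_items):
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    history: list[EpochRecord] = []
    best = {"dice": -1.0, "state": model.state_dict()}
    since_improve = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_items))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_items[i] for i in order[start:start + cfg.batch_size]]
            if augment_fn is not None:
                batch = [augment_fn(x, t, rng) for x, t in batch]
            xs = np.stack([b[0] for b in batch])
            ts = np.stack([b[1] for b in batch])
            logits = forward(model, xs)
            loss = segmentation_loss(logits, ts, cfg.loss_weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            # release the graph before the next forward builds a new one,
            # keeping peak memory at a single graph's worth
            del logits, loss
        model.eval()
        val_dice = _val_score(predict, val_items, score)
        history.append(EpochRecord(epoch, float(np.mean(losses)),
                                   val_dice, opt.lr))
        if log:
            log(f"epoch={epoch} loss={np.mean(losses):.4f} "
                f"val_dice={val_dice:.4f} lr={opt.lr:g}")
        if val_dice > best["dice"]:
            best = {"dice": val_dice, "state": model.state_dict()}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                since_improve = 0
    return history, best


def evaluate(predict: Callable[[np.ndarray], np.ndarray],
             test_items: Sequence, task: str = "seg",
             scan_ids: Sequence[str] | None = None) -> dict:
    """Per-sample and aggregate DSC/IoU/Precision/Recall.

    task "seg": binary spine-vs-background; "recog": macro over vertebra
    classes present in each sample's truth.
    """
    if task not in ("seg", "recog"):
        raise ValueError("task must be 'seg' or 'recog'")
    if not len(test_items):
        raise ValueError("test set must be nonempty")
    rows = []
    for i, (x, t) in enumerate(test_items):
        pred = predict(x)
        sid = scan_ids[i] if scan_ids else f"sample_{i:03d}"
        if task == "seg":
            rep = metrics.binary_report(pred > 0, np.asarray(t) > 0)
            rows.append({"scan_id": sid, "class": 1, **rep})
        else:
            rep = metrics.macro_report(pred, t)
            for r in rep["per_class"]:
                rows.append({"scan_id": sid, **{k: v for k, v in r.items()
                                                if k != "absent"}})
    agg = {m: float(np.mean([r[m] for r in rows]))
           for m in ("dice", "iou", "precision", "recall")}
    return {"rows": rows, "aggregate": agg}


def write_history(history: list[EpochRecord], path) -> None:
    """Training log as line-delimited JSON."""
    with open(path, "w") as fh:
        for rec in history:
            fh.write(json.dumps(rec.__dict__) + "\n")
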