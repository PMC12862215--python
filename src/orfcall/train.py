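"""Training loop: masked cross-entropy, Adam, plateau LR halving,
early stopping, best-by-validation checkpointing, and stratified
coding/noncoding batch composition.

"Improvement" throughout means a validation loss lower than the best
seen so far by at least 1e-6; both the scheduler and the early-stopping
counter reset on improvement, and the scheduler's counter also resets
when it fires a learning-rate reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .layers import Adam
from .model import SiteLabeler
from .records import EncodedSample

logger = logging.getLogger(__name__)

IMPROVEMENT_TOL = 1e-6


@dataclass
class TrainConfig:
    max_epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    early_stop_patience: int = 5
    seed: int = 0
    mix_noncoding: bool = True

    def __post_init__(self) -> None:
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.early_stop_patience < self.plateau_patience:
            raise ValueError("early_stop_patience must be >= plateau_patience")


def stratified_batches(
    samples: Sequence[EncodedSample], batch_size: int, seed: int
) -> List[List[int]]:
    """Index batches with the global coding fraction held per batch.

    Coding and noncoding samples are shuffled separately, then dealt out
    so that the running number of coding samples tracks the global
    coding fraction (cumulative rounding): any batch's coding fraction
    deviates from the global one by at most 1/batch_size.  Every sample
    appears exactly once per epoch.  Deterministic given the seed.
    """
    if not samples:
        raise ValueError("no samples to batch")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(seed)
    coding = [i for i, s in enumerate(samples) if s.biotype == "coding"]
    noncoding = [i for i, s in enumerate(samples) if s.biotype != "coding"]
    rng.shuffle(coding)
    rng.shuffle(noncoding)
    n = len(samples)
    frac = len(coding) / n
    batches: List[List[int]] = []
    done = 0
    taken_coding = 0
    while done < n:
        size = min(batch_size, n - done)
        target = int(round(frac * (done + size)))
        k = min(max(target - taken_coding, 0), size, len(coding) - taken_coding)
        k = max(k, size - (len(noncoding) - (done - taken_coding)))
        batch = coding[taken_coding : taken_coding + k]
        batch += noncoding[done - taken_coding : done - taken_coding + size - k]
        rng.shuffle(batch)
        batches.append(batch)
        taken_coding += k
        done += size
    return batches


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _position_mask(labels_shape, valid_lengths) -> np.ndarray:
    B, L = labels_shape
    return np.arange(L)[None, :] < np.asarray(valid_lengths)[:, None]


def masked_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, valid_lengths: Sequence[int]
) -> float:
    """Mean of -log p(true class) over non-padding positions only."""
    loss, _ = masked_cross_entropy_grad(logits, labels, valid_lengths,
                                        want_grad=False)
    return loss


def masked_cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray, valid_lengths: Sequence[int],
    want_grad: bool = True,
):
    logits = np.asarray(logits)
    labels = np.asarray(labels)
    if logits.shape[:2] != labels.shape:
        raise ValueError("logits/labels shape mismatch")
    mask = _position_mask(labels.shape, valid_lengths)
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError("no unmasked positions")
    probs = _softmax(logits.astype(np.float64, copy=False))
    b_idx, l_idx = np.nonzero(mask)
    p_true = probs[b_idx, l_idx, labels[b_idx, l_idx]]
    loss = float(-np.log(np.maximum(p_true, 1e-300)).mean())
    if not want_grad:
        return loss, None
    grad = probs.astype(np.float32)
    grad[b_idx, l_idx, labels[b_idx, l_idx]] -= 1.0
    grad *= mask[:, :, None].astype(np.float32) / n_valid
    return loss, grad


class PlateauController:
    """Tracks validation loss: signals LR reductions and early stopping."""

    def __init__(self, plateau_patience: int, early_stop_patience: int,
                 tol: float = IMPROVEMENT_TOL):
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.tol = tol
        self.best = np.inf
        self.best_epoch = -1
        self._bad_sched = 0
        self._bad_stop = 0

    def update(self, loss: float, epoch: int) -> Dict[str, bool]:
        improved = loss < self.best - self.tol
        reduce_lr = False
        if improved:
            self.best = loss
            self.best_epoch = epoch
            self._bad_sched = 0
            self._bad_stop = 0
        else:
            self._bad_sched += 1
            self._bad_stop += 1
            if self._bad_sched >= self.plateau_patience:
                reduce_lr = True
                self._bad_sched = 0
        stop = self._bad_stop >= self.early_stop_patience
        return {"improved": improved, "reduce_lr": reduce_lr, "stop": stop}


@dataclass
class TrainResult:
    model: SiteLabeler
    history: List[Dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf


def _make_batch(samples: Sequence[EncodedSample], indices: Sequence[int]):
    """Stack a batch, trimming shared padding down to the batch maximum
    valid length (labels beyond each sample's own length stay masked)."""
    lengths = [samples[i].valid_length for i in indices]
    l_batch = max(lengths)
    tokens = np.stack([samples[i].tokens[:l_batch] for i in indices]).astype(np.int64)
    labels = np.stack([samples[i].labels[:l_batch] for i in indices]).astype(np.int64)
    return tokens, labels, lengths


def evaluate_loss(model: SiteLabeler, samples: Sequence[EncodedSample],
                  batch_size: int = 8) -> float:
    """Masked cross-entropy over a sample set in evaluation mode."""
    total, n_total = 0.0, 0
    order = sorted(range(len(samples)), key=lambda i: samples[i].valid_length)
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        tokens, labels, lengths = _make_batch(samples, idx)
        logits = model.forward(tokens, lengths=lengths, train=False)
        loss = masked_cross_entropy(logits, labels, lengths)
        n = int(sum(lengths))
        total += loss * n
        n_total += n
    return total / n_total


def train(
    model: SiteLabeler,
    train_samples: Sequence[EncodedSample],
    val_samples: Sequence[EncodedSample],
    config: Optional[TrainConfig] = None,
) -> TrainResult:
    """Train to minimise masked cross-entropy; return the best epoch's weights.

    The learning rate halves after ``plateau_patience`` consecutive
    non-improving validation epochs, training stops after
    ``early_stop_patience`` such epochs (or ``max_epochs``), and the
    returned model carries the weights of the epoch with the lowest
    validation loss.
    """
    config = config or TrainConfig()
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    optimizer = Adam(model.params(), lr=config.learning_rate)
    controller = PlateauController(config.plateau_patience,
                                   config.early_stop_patience)
    result = TrainResult(model=model)
    best_state = None
    for epoch in range(1, config.max_epochs + 1):
        batches = stratified_batches(train_samples, config.batch_size,
                                     seed=config.seed + epoch)
        epoch_loss, epoch_n = 0.0, 0
        for idx in batches:
            tokens, labels, lengths = _make_batch(train_samples, idx)
            logits = model.forward(tokens, lengths=lengths, train=True)
            loss, grad = masked_cross_entropy_grad(logits, labels, lengths)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}"
                )
            optimizer.zero_grad()
            model.backward(grad)
            optimizer.step()
            n = int(sum(lengths))
            epoch_loss += loss * n
            epoch_n += n
        val_loss = evaluate_loss(model, val_samples)
        signal = controller.update(val_loss, epoch)
        if signal["improved"]:
            best_state = model.state_dict()
        result.history.append(
            {"epoch": epoch, "train_loss": epoch_loss / epoch_n,
             "val_loss": val_loss, "lr": optimizer.lr}
        )
        logger.info("epoch %d train %.4f val %.4f lr %.2e", epoch,
                    epoch_loss / epoch_n, val_loss, optimizer.lr)
        if signal["reduce_lr"]:
            optimizer.lr *= config.plateau_factor
            logger.info("reducing learning rate to %.2e", optimizer.lr)
        if signal["stop"]:
            logger.info("early stopping at epoch %d", epoch)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    result.best_epoch = controller.best_epoch
    result.best_val_loss = controller.best
    return result


def write_history_tsv(history: List[Dict[str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\tlr\n")
        for row in history:
            fh.write(f"{row['epoch']}\t{row['train_loss']:.6f}\t"
                     f"{row['val_loss']:.6f}\t{row['lr']:.6g}\n")
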