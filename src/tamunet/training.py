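"""BCE training loop with cosine-annealed Adam.

Images enter the network as float32 in [0, 1] (uint8 / 255).  The learning
rate follows per-epoch cosine annealing from ``lr_max`` (1e-4) at epoch 0 to
``lr_min`` (1e-7) at the final epoch.  Training samples are augmented online
(fresh random rotation/scaling per load); validation runs un-augmented in
eval mode, and the best-validation-Dice weights are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .metrics import metrics2d
from .preprocessing import SliceSample, augment_pair

BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 4
    lr_max: float = 1e-4
    lr_min: float = 1e-7
    seed: int = 0
    augment: bool = True
    threshold: float = 0.5
    # length of the cosine anneal; defaults to `epochs`.  A short sanity run
    # can truncate the full-length schedule (anneal_epochs > epochs) instead
    # of compressing the entire decay into a few epochs.
    anneal_epochs: int | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr_min < self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if self.anneal_epochs is not None and self.anneal_epochs < self.epochs:
            raise ValueError("anneal_epochs must be >= epochs")

    @property
    def schedule_length(self) -> int:
        return self.anneal_epochs if self.anneal_epochs is not None else self.epochs


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    val_dice: float
    val_iou: float
    lr: float


def bce_loss(predictions, targets, eps: float = BCE_EPS):
    """Mean binary cross-entropy over all pixels (probabilities clamped to
    [eps, 1-eps] so saturated predictions stay finite)."""
    p = nn._as_tensor(predictions)
    t = nn._as_tensor(targets)
    if p.shape != t.shape:
        raise ValueError(f"prediction {p.shape} / target {t.shape} shape mismatch")
    p = nn.clamp(p, eps, 1.0 - eps)
    ll = t * nn.log(p) + (1.0 - t) * nn.log(1.0 - p)
    return -nn.mean(ll)


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """lr(e) = lr_min + (lr_max - lr_min)(1 + cos(pi e/(E-1)))/2 over the
    schedule length E; equals lr_max at epoch 0 and lr_min at the final
    scheduled epoch."""
    E = config.schedule_length
    if not 0 <= epoch < E:
        raise ValueError(f"epoch {epoch} outside [0, {E})")
    if E == 1:
        return config.lr_max
    frac = epoch / (E - 1)
    return config.lr_min + 0.5 * (config.lr_max - config.lr_min) * (1 + math.cos(math.pi * frac))


def _batch_arrays(samples, rng=None, augment=False):
    imgs, masks = [], []
    for s in samples:
        img, mask = s.image, s.mask
        if augment:
            img, mask = augment_pair(img, mask, rng)
        imgs.append(img.astype(np.float32) / 255.0)
        masks.append(mask.astype(np.float32))
    x = np.stack(imgs)[:, None]   # (N, 1, H, W)
    y = np.stack(masks)[:, None]
    return x, y


def evaluate(model, samples, threshold: float = 0.5, batch_size: int = 4):
    """Mean per-slice Dice and liver IoU on un-augmented samples (eval mode)."""
    model.eval()
    dices, ious = [], []
    with nn.no_grad():
        for lo in range(0, len(samples), batch_size):
            batch = samples[lo:lo + batch_size]
            x, y = _batch_arrays(batch)
            pred = model(x).numpy()
            for p, t in zip(pred, y):
                m = metrics2d((p[0] >= threshold).astype(np.uint8),
                              t[0].astype(np.uint8))
                dices.append(m.dice)
                ious.append(m.iou_liver)
    return float(np.mean(dices)), float(np.mean(ious))


def train(model, train_samples, val_samples, config: TrainConfig):
    """Seeded training loop; returns (model-with-best-weights, epoch logs)."""
    if not train_samples:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr_max)
    logs: list[EpochLog] = []
    best_dice, best_state = -1.0, None
    n = len(train_samples)
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            batch = [train_samples[i] for i in order[lo:lo + config.batch_size]]
            x, y = _batch_arrays(batch, rng, augment=config.augment)
            pred = model(x)
            loss = bce_loss(pred, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        if val_samples:
            val_dice, val_iou = evaluate(model, val_samples, config.threshold,
                                         config.batch_size)
        else:
            val_dice = val_iou = float("nan")
        logs.append(EpochLog(epoch, float(np.mean(losses)), val_dice, val_iou, lr))
        if val_samples and val_dice > best_dice:
            best_dice = val_dice
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, logs


def overfit_single_batch(model, samples, steps: int = 200, lr: float = 1e-3,
                         seed: int = 0):
    """Repeatedly fit one fixed batch (no augmentation); returns the BCE
    trajectory.  A sanity oracle: the network must be able to drive the loss
    near zero on data it has memorized."""
    x, y = _batch_arrays(samples)
    opt = nn.Adam(model.parameters(), lr=lr)
    model.train()
    trajectory = []
    for _ in range(steps):
        loss = bce_loss(model(x), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trajectory.append(loss.item())
    return trajectory


def predict_slices(model, samples, threshold: float = 0.5, batch_size: int = 4):
    """Binary masks for a list of SliceSamples, Z indices preserved.

    Returns a list of (case_id, z, mask) aligned with the input order.
    """
    model.eval()
    out = []
    with nn.no_grad():
        for lo in range(0, len(samples), batch_size):
            batch = samples[lo:lo + batch_size]
            x, _ = _batch_arrays(batch)
            pred = model(x).numpy()
            for s, p in zip(batch, pred):
                out.append((s.case_id, s.z, (p[0] >= threshold).astype(np.uint8)))
    return out
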