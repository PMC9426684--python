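"""Training loop for the NumPy models: weighted losses with analytic
gradients, Adam/RMSProp optimisers, the exponential learning-rate schedule
and best-weight early stopping.

Schedule: the learning rate is held for the first 5 epochs and then
multiplied by exp(-0.1) every epoch (epoch numbering is 1-based, so
lr(7) = lr0 * exp(-0.2)).  Early stopping monitors the training loss by
default (a validation mode is available): if ``patience`` epochs elapse
without improvement, training ceases and the best epoch's weights are
restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from ..metrics import ClassWeights, DiceWeights


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"  # or "rmsprop"
    learning_rate: float = 1e-3
    decay_rate: float = 0.1  # per-epoch exponential factor exp(-decay_rate)
    decay_after_epochs: int = 5
    patience: int = 30
    max_epochs: int = 100
    batch_size: int = 32
    augment_rotation_deg: float = 60.0
    augment_enabled: bool = False
    monitor: str = "train"  # or "val"
    seed: int = 0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError("optimizer must be 'adam' or 'rmsprop'")


def learning_rate_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate for a 1-based epoch index under the exponential decay."""
    steps = max(0, epoch - cfg.decay_after_epochs)
    return cfg.learning_rate * float(np.exp(-cfg.decay_rate * steps))


# -- losses with gradients -------------------------------------------------


def weighted_dice_loss_grad(y, y_hat, weights: DiceWeights | None = None):
    """Batch channel-weighted Dice loss and its gradient w.r.t. ``y_hat``.

    ``y``/``y_hat`` are (N, 4, H, W); the per-channel Dice ratio pools the
    batch and spatial axes, mirroring the scalar loss in
    :func:`cinescar.metrics.weighted_dice_loss`.
    """
    weights = weights or DiceWeights()
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape[1] != 4:
        raise ValueError("expected 4 channels")
    eps = weights.epsilon
    loss = 0.0
    grad = np.zeros_like(y_hat)
    for i, beta in enumerate(weights.beta):
        num = 2.0 * np.sum(y[:, i] * y_hat[:, i]) + eps
        den = np.sum(y[:, i]) + np.sum(y_hat[:, i]) + eps
        loss += beta * (1.0 - num / den)
        # d(1 - num/den)/dyhat = -(2*y*den - num) / den^2
        grad[:, i] = -beta * (2.0 * y[:, i] * den - num) / den**2
    return float(loss), grad


def weighted_ce_loss_grad(y, p, weights: ClassWeights | None = None):
    """Weighted binary cross-entropy and gradient w.r.t. the sigmoid output.

    ``y`` is (N,) binary labels, ``p`` is (N, 1) or (N,) predicted
    probabilities of class 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    p_arr = np.asarray(p, dtype=float)
    flat = p_arr.ravel()
    lam = np.asarray(weights.lambda_ if weights is not None else (1.0, 1.0))
    eps = 1e-7
    pc = np.clip(flat, eps, 1.0 - eps)
    n = len(y)
    loss = float(-np.mean(np.where(y == 1, lam[1] * np.log(pc), lam[0] * np.log(1.0 - pc))))
    grad = np.where(y == 1, -lam[1] / pc, lam[0] / (1.0 - pc)) / n
    return loss, grad.reshape(p_arr.shape)


# -- optimisers ------------------------------------------------------------


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for p in params if p.trainable]
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


class _RMSProp:
    def __init__(self, params, rho=0.9, eps=1e-8):
        self.params = [p for p in params if p.trainable]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.rho, self.eps = rho, eps

    def step(self, lr):
        for p, v in zip(self.params, self.v):
            v *= self.rho
            v += (1 - self.rho) * p.grad**2
            p.value -= lr * p.grad / (np.sqrt(v) + self.eps)


# -- augmentation ----------------------------------------------------------


def augment(images, masks=None, rotation_deg: float = 60.0, rng=None):
    """Per-sample random rotation (uniform in +/-rotation_deg) and 1-99
    percentile intensity normalisation to (0, 1).

    ``images`` is (N, C, H, W); ``masks`` (N, H, W) integer labels rotates
    with nearest-neighbour so no new label values appear.
    """
    rng = rng or np.random.default_rng(0)
    images = np.asarray(images, dtype=float)
    out_imgs = np.empty_like(images)
    out_masks = None if masks is None else np.empty_like(np.asarray(masks))
    for n in range(images.shape[0]):
        angle = rng.uniform(-rotation_deg, rotation_deg)
        img = ndi.rotate(
            images[n], angle, axes=(1, 2), reshape=False, order=1, mode="nearest"
        )
        lo, hi = np.percentile(img, (1, 99))
        if hi > lo:
            img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
        else:
            img = np.zeros_like(img)
        out_imgs[n] = img
        if out_masks is not None:
            out_masks[n] = ndi.rotate(
                masks[n], angle, axes=(0, 1), reshape=False, order=0, mode="constant", cval=0
            )
    return (out_imgs, out_masks) if masks is not None else out_imgs


def one_hot_masks(masks, n_classes: int = 4) -> np.ndarray:
    """(N, H, W) integer labels -> (N, C, H, W) one-hot."""
    masks = np.asarray(masks, dtype=int)
    return np.transpose(np.eye(n_classes)[masks], (0, 3, 1, 2))


# -- the loop --------------------------------------------------------------


def train_model(model, data, loss: str = "dice", cfg: TrainConfig | None = None, loss_weights=None, val_data=None):
    """Train a NumPy model; returns ``(history, best_weights)``.

    ``data`` is ``(x, y)``: for ``loss="dice"`` ``y`` is (N, H, W) integer
    masks (one-hot encoded internally); for ``loss="wce"`` ``y`` is (N,)
    binary labels and ``loss_weights`` should be :class:`ClassWeights`
    computed from the *training* class counts.  The best-loss weights are
    restored into the model before returning.
    """
    cfg = cfg or TrainConfig()
    x, y = data
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    if hasattr(model, "set_rng"):
        model.set_rng(np.random.default_rng(cfg.seed + 1))
    if loss == "dice":
        y_enc = one_hot_masks(y)
    elif loss == "wce":
        y_enc = np.asarray(y, dtype=float).ravel()
    else:
        raise ValueError("loss must be 'dice' or 'wce'")

    opt_cls = _Adam if cfg.optimizer == "adam" else _RMSProp
    optimizer = opt_cls(model.parameters())
    best_loss, best_weights, best_epoch = np.inf, model.get_weights(), 0
    rows = []
    since_best = 0
    for epoch in range(1, cfg.max_epochs + 1):
        lr = learning_rate_at_epoch(cfg, epoch)
        order = rng.permutation(len(x))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x[idx]
            if loss == "dice":
                yb = y_enc[idx]
                if cfg.augment_enabled:
                    xb, mb = augment(xb, np.asarray(y)[idx], cfg.augment_rotation_deg, rng)
                    yb = one_hot_masks(mb)
            else:
                yb = y_enc[idx]
                if cfg.augment_enabled:
                    xb = augment(xb, None, cfg.augment_rotation_deg, rng)
            model.zero_grad()
            pred = model.forward(xb, train=True)
            if loss == "dice":
                batch_loss, grad = weighted_dice_loss_grad(yb, pred, loss_weights)
            else:
                batch_loss, grad = weighted_ce_loss_grad(yb, pred, loss_weights)
            model.backward(grad)
            optimizer.step(lr)
            epoch_loss += batch_loss
            n_batches += 1
        epoch_loss /= n_batches
        monitored = epoch_loss
        val_loss = np.nan
        if val_data is not None:
            xv, yv = val_data
            pv = model.forward(np.asarray(xv, dtype=float), train=False)
            if loss == "dice":
                val_loss, _ = weighted_dice_loss_grad(one_hot_masks(yv), pv, loss_weights)
            else:
                val_loss, _ = weighted_ce_loss_grad(yv, pv, loss_weights)
            if cfg.monitor == "val":
                monitored = val_loss
        rows.append({"epoch": epoch, "lr": lr, "train_loss": epoch_loss, "val_loss": val_loss})
        if monitored < best_loss:
            best_loss, best_weights, best_epoch = monitored, model.get_weights(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.set_weights(best_weights)
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_loss"] = best_loss
    return history, best_weights
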