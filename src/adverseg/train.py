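"""Alternating adversarial training of the segmentation networks.

Per batch, the discriminator is updated first (minimising the negated
feature-MAE term, i.e. maximising the discrepancy between real and predicted
feature pyramids, with the generator output detached), then the generator
(minimising the weighted Dice + feature-MAE objective through the frozen
discriminator). All randomness — shuffling and network initialisation —
derives from the training seed, so single-threaded CPU runs are
reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from . import losses as L
from . import metrics as M
from .models import Discriminator, Generator
from .nn import Tensor, make_optimizer, no_grad


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Learning rate, weight decay and momentum default to 1e-4, 1e-4 and 0.9;
    the optimizer is stochastic gradient descent with momentum (``adam``
    available by name).
    """

    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    momentum: float = 0.9
    optimizer: str = "sgd"
    batch_size: int = 1
    epochs: int = 14
    loss_weights: L.LossWeights = L.LossWeights()
    seed: int = 0
    device: str = "cpu"
    d_steps_per_g_step: int = 1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.d_steps_per_g_step < 1:
            raise ValueError("d_steps_per_g_step must be >= 1")


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch learning curves (the loss/Dice training record)."""

    epoch: list[int] = dataclasses.field(default_factory=list)
    gen_loss: list[float] = dataclasses.field(default_factory=list)
    disc_loss: list[float] = dataclasses.field(default_factory=list)
    train_dice: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    val_dice: list[float] = dataclasses.field(default_factory=list)

    def append(self, **kw) -> None:
        for k, v in kw.items():
            getattr(self, k).append(v)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(dataclasses.asdict(self))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _stack(items) -> tuple[np.ndarray, np.ndarray]:
    """Stack (image, mask) pairs into (N,1,H,W) float batches."""
    images, masks = [], []
    for it in items:
        img, msk = (it.image, it.mask) if hasattr(it, "image") else it
        images.append(np.asarray(img, dtype=np.float32))
        masks.append(np.asarray(msk, dtype=np.float32))
    x = np.stack(images)[:, None]
    y = np.stack(masks)[:, None]
    return x, y


def _check_finite(value: float, term: str, epoch: int) -> None:
    if not math.isfinite(value):
        raise FloatingPointError(
            f"non-finite {term} ({value}) at epoch {epoch}; aborting")


def train(gen: Generator, disc: Discriminator, train_set: Sequence,
          val_set: Sequence, config: TrainConfig = TrainConfig()
          ) -> tuple[Generator, Discriminator, TrainHistory]:
    """Run alternating adversarial training; returns the trained networks
    and the per-epoch history."""
    if not len(train_set):
        raise ValueError("empty training set")
    rng = np.random.default_rng(int(config.seed))
    w = config.loss_weights
    g_opt = make_optimizer(config.optimizer, gen.parameters(),
                           config.learning_rate, config.momentum,
                           config.weight_decay)
    d_opt = make_optimizer(config.optimizer, disc.parameters(),
                           config.learning_rate, config.momentum,
                           config.weight_decay)
    history = TrainHistory()
    n = len(train_set)
    for epoch in range(1, config.epochs + 1):
        gen.train()
        disc.train()
        order = rng.permutation(n)
        g_losses, d_losses, dices = [], [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, y = _stack([train_set[i] for i in idx])
            adversarial = w.delta > 0
            # single generator forward per batch: its detached output feeds
            # the discriminator update, the graph feeds the generator update
            pred = gen(x)
            # -- discriminator step(s): maximise feature discrepancy
            d_val = 0.0
            if adversarial:
                fake = pred.data
                for _ in range(config.d_steps_per_g_step):
                    feats_real, _ = disc(x, y)
                    feats_fake, _ = disc(x, fake)
                    d_loss = L.discriminator_objective(feats_real,
                                                       feats_fake, w)
                    d_val = float(d_loss.data) if isinstance(d_loss, Tensor) \
                        else float(d_loss)
                    _check_finite(d_val, "discriminator loss", epoch)
                    if isinstance(d_loss, Tensor) and d_loss.requires_grad:
                        d_opt.zero_grad()
                        d_loss.backward()
                        d_opt.step()
            # -- generator step through the (freshly updated) discriminator
            if adversarial:
                feats_real, _ = disc(x, y)
                feats_fake, _ = disc(x, pred)
                g_loss = L.generator_objective(pred, y, feats_real,
                                               feats_fake, w)
            else:
                g_loss = w.lam * L.dice_term_batch(pred, y, w.eps)
            g_val = float(g_loss.data)
            _check_finite(g_val, "generator loss", epoch)
            g_opt.zero_grad()
            d_opt.zero_grad()  # discriminator grads from this pass are unused
            g_loss.backward()
            g_opt.step()
            g_losses.append(g_val)
            d_losses.append(d_val)
            dices.append(-L.dice_term_batch(pred.data, y, w.eps))
        val_loss, val_dice = _validate(gen, disc, val_set, config)
        _check_finite(val_loss, "validation loss", epoch)
        history.append(epoch=epoch,
                       gen_loss=float(np.mean(g_losses)),
                       disc_loss=float(np.mean(d_losses)),
                       train_dice=float(np.mean(dices)),
                       val_loss=val_loss,
                       val_dice=val_dice)
    return gen, disc, history


def _validate(gen: Generator, disc: Discriminator, val_set: Sequence,
              config: TrainConfig) -> tuple[float, float]:
    """Soft-Dice validation metrics (no parameter updates)."""
    if not len(val_set):
        return float("nan"), float("nan")
    gen.eval()
    disc.eval()
    w = config.loss_weights
    losses, dices = [], []
    with no_grad():
        for start in range(0, len(val_set), config.batch_size):
            batch = [val_set[i] for i in
                     range(start, min(start + config.batch_size,
                                      len(val_set)))]
            x, y = _stack(batch)
            pred = gen(x).data
            feats_real, _ = disc(x, y)
            feats_fake, _ = disc(x, pred)
            losses.append(L.generator_objective(
                pred, y, [f.data for f in feats_real],
                [f.data for f in feats_fake], w))
            dices.append(-L.dice_term_batch(pred, y, w.eps))
    return float(np.mean(losses)), float(np.mean(dices))


def predict(gen: Generator, images, threshold: float = 0.5
            ) -> tuple[np.ndarray, np.ndarray]:
    """Probability maps and thresholded binary masks for one image or a
    batch. Inputs whose height/width are not divisible by 8 are reflect-
    padded symmetrically and the output is cropped back."""
    arr = np.asarray(images, dtype=np.float32)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("predict expects (H, W) or (N, H, W) input")
    n, h, w = arr.shape
    ph = (-h) % 8
    pw = (-w) % 8
    padded = np.pad(arr, ((0, 0), (ph // 2, ph - ph // 2),
                          (pw // 2, pw - pw // 2)), mode="reflect") \
        if (ph or pw) else arr
    gen.eval()
    with no_grad():
        prob = gen(padded[:, None]).data[:, 0]
    if ph or pw:
        prob = prob[:, ph // 2:ph // 2 + h, pw // 2:pw // 2 + w]
    masks = (prob >= threshold).astype(np.uint8)
    if single:
        return prob[0], masks[0]
    return prob, masks


def evaluate(gen: Generator, test_set: Sequence, spacing=(1.0, 1.0),
             threshold: float = 0.5) -> M.MetricReport:
    """Binarize the generator's probability maps and compute the full
    per-slice metric report over a test set."""
    if not len(test_set):
        raise ValueError("empty test set")
    preds, truths = [], []
    for it in test_set:
        img, msk = (it.image, it.mask) if hasattr(it, "image") else it
        _, mask = predict(gen, np.asarray(img), threshold)
        preds.append(mask)
        truths.append(np.asarray(msk).astype(np.uint8))
    return M.evaluate_masks(preds, truths, spacing)


def split_dataset(items: Sequence, fractions=(0.7, 0.15, 0.15), seed: int = 0):
    """Shuffle and split into train/val/test parts by the given fractions."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(int(seed))
    order = rng.permutation(len(items))
    n_train = int(round(fractions[0] * len(items)))
    n_val = int(round(fractions[1] * len(items)))
    take = lambda ix: [items[i] for i in ix]  # noqa: E731
    return (take(order[:n_train]), take(order[n_train:n_train + n_val]),
            take(order[n_train + n_val:]))


def plot_history(history: TrainHistory, path: str | Path) -> None:
    """Loss and Dice learning curves, one panel each."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(history.epoch, history.gen_loss, label="generator")
    ax1.plot(history.epoch, history.disc_loss, label="discriminator")
    ax1.plot(history.epoch, history.val_loss, label="validation")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("loss")
    ax1.legend()
    ax2.plot(history.epoch, history.train_dice, label="train")
    ax2.plot(history.epoch, history.val_dice, label="validation")
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("soft Dice")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_checkpoint(path: str | Path, gen: Generator, disc: Discriminator,
                    config: TrainConfig | None = None,
                    epoch: int | None = None) -> None:
    """Write both networks' weights (and configs) to an ``.npz`` archive."""
    import json

    payload = {}
    for k, v in gen.state_dict().items():
        payload["gen." + k] = v
    for k, v in disc.state_dict().items():
        payload["disc." + k] = v
    meta = {
        "gen_config": gen.config.to_json(),
        "disc_config": disc.config.to_json(),
        "epoch": epoch,
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["loss_weights"] = dataclasses.asdict(config.loss_weights)
        meta["train_config"] = cfg
    payload["meta.json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[Generator, Discriminator, dict]:
    """Rebuild both networks from a checkpoint archive."""
    import json

    from .models import (DiscriminatorConfig, GeneratorConfig,
                         build_discriminator, build_generator)

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta.json"]).decode())
        gen = build_generator(GeneratorConfig.from_json(meta["gen_config"]))
        disc = build_discriminator(
            DiscriminatorConfig.from_json(meta["disc_config"]))
        gen_state = {k[4:]: data[k] for k in data.files if k.startswith("gen.")}
        disc_state = {k[5:]: data[k] for k in data.files
                      if k.startswith("disc.")}
    gen.load_state_dict(gen_state)
    disc.load_state_dict(disc_state)
    return gen, disc, meta
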