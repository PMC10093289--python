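"""Composite adversarial segmentation objective.

The generator minimises a weighted sum of two terms over a batch of N pairs:

* a smoothed negative Dice term per pair,
  ``-(2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps)``, computed on the soft
  probability map so it stays differentiable; and
* an L1 (mean-absolute-error) term between the discriminator's feature
  pyramids for the real pair (x, y) and the predicted pair (x, G(x)).

The discriminator is trained adversarially to *maximise* the feature
discrepancy, so its minimised loss is the exact negation of the generator's
MAE component; the Dice term does not involve the discriminator. Every
function accepts either autodiff tensors (training) or plain numpy arrays
(returns a float).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .nn import Tensor, tabs, tlog


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """Weights of the composite objective: ``lam`` on the Dice term,
    ``delta`` on the feature-MAE term, ``eps`` the Dice smoothing constant."""

    lam: float = 1.0
    delta: float = 1.0
    eps: float = 1.0

    def __post_init__(self):
        if self.lam < 0 or self.delta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be strictly positive")


def _is_plain(*xs) -> bool:
    return all(not isinstance(x, Tensor) for x in xs)


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return Tensor(arr)


def _check_same_shape(a, b, what: str) -> None:
    sa = a.shape if isinstance(a, Tensor) else np.asarray(a).shape
    sb = b.shape if isinstance(b, Tensor) else np.asarray(b).shape
    if tuple(sa) != tuple(sb):
        raise ValueError(f"{what}: shape mismatch {tuple(sa)} vs {tuple(sb)}")


def dice_term(pred, truth, eps: float = 1.0):
    """Smoothed negative Dice of one prediction/truth pair; in [-1, 0].

    For identical masks (including the empty/empty limit) the value is -1.
    """
    if eps <= 0:
        raise ValueError("eps must be strictly positive")
    _check_same_shape(pred, truth, "dice_term")
    plain = _is_plain(pred, truth)
    p, t = _as_tensor(pred), _as_tensor(truth)
    num = 2.0 * (p * t).sum() + eps
    den = p.sum() + t.sum() + eps
    out = -(num / den)
    return float(out.data) if plain else out


def dice_term_batch(pred, truth, eps: float = 1.0):
    """Mean of per-item Dice terms over a (N, 1, H, W) batch."""
    _check_same_shape(pred, truth, "dice_term_batch")
    plain = _is_plain(pred, truth)
    p, t = _as_tensor(pred), _as_tensor(truth)
    axes = tuple(range(1, p.ndim))
    num = 2.0 * (p * t).sum(axis=axes) + eps
    den = p.sum(axis=axes) + t.sum(axis=axes) + eps
    out = -(num / den).mean()
    return float(out.data) if plain else out


def mae_term(feats_real: Sequence, feats_fake: Sequence):
    """Mean absolute difference between two feature pyramids.

    Averaged within each level, then across levels, so that small deep maps
    and large shallow maps contribute equally.
    """
    if len(feats_real) != len(feats_fake):
        raise ValueError(
            f"pyramids have {len(feats_real)} vs {len(feats_fake)} levels")
    if not len(feats_real):
        raise ValueError("empty feature pyramid")
    plain = _is_plain(*feats_real, *feats_fake)
    total = None
    for k, (fr, ff) in enumerate(zip(feats_real, feats_fake)):
        _check_same_shape(fr, ff, f"mae_term level {k}")
        level = tabs(_as_tensor(fr) - _as_tensor(ff)).mean()
        total = level if total is None else total + level
    out = total * (1.0 / len(feats_real))
    return float(out.data) if plain else out


def generator_objective(pred, truth, feats_real, feats_fake,
                        weights: LossWeights = LossWeights()):
    """Batch objective minimised by the generator:
    ``lam * mean(dice) + delta * mae``."""
    plain = _is_plain(pred, truth, *feats_real, *feats_fake)
    out = weights.lam * dice_term_batch(pred, truth, weights.eps) \
        + weights.delta * mae_term(feats_real, feats_fake)
    return float(out.data) if isinstance(out, Tensor) and plain else out


def discriminator_objective(feats_real, feats_fake,
                            weights: LossWeights = LossWeights()):
    """Loss minimised by the discriminator: the negated, delta-weighted MAE
    term (it maximises the feature discrepancy). The Dice term does not
    depend on the discriminator and is excluded."""
    plain = _is_plain(*feats_real, *feats_fake)
    out = -(weights.delta * mae_term(feats_real, feats_fake))
    return float(out.data) if isinstance(out, Tensor) and plain else out


def conventional_gan_value(d_real, d_fake):
    """Value of the classical two-player GAN objective
    ``E[log D(x)] + E[log(1 - D(G(z)))]`` for given decision probabilities.

    Documented reference form only; the segmentation networks train on the
    Dice + feature-MAE objective instead and never optimise this quantity.
    """
    plain = _is_plain(d_real, d_fake)
    dr, df = _as_tensor(d_real), _as_tensor(d_fake)
    out = tlog(dr).mean() + tlog(1.0 - df).mean()
    return float(out.data) if plain else out
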