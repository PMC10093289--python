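"""Synthetic CT-like slice/mask phantoms for kidney segmentation experiments.

Each phantom slice contains zero, one or two bright kidney-like regions —
randomly rotated ellipses — on a darker, noisy background. With configurable
probability a region encloses a hollow interior (the collecting system), an
area that takes background intensity and is *excluded* from the foreground
label. This reproduces the hardest structure of the real task: a boundary
with no intensity support on the outside and an interior cavity that must
not be labelled kidney. Slices with two regions place one ellipse in each
image half, mimicking left/right kidney anatomy; single-region slices pick a
side at random.

Generation is deterministic per (seed, index) pair, so datasets are
order-independent and reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration violates its invariants."""


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom distribution.

    Attributes
    ----------
    image_size:
        Pixels per side of the square slice; must be >= 32 and divisible by 8
        (the segmentation network pools three times).
    n_regions_choices:
        Allowed kidney-region counts per slice, a subset of {0, 1, 2},
        sampled uniformly.
    region_axis_range:
        (min, max) ellipse semi-axis length in pixels.
    hollow_prob:
        Probability that a region contains an excluded hollow interior.
    hollow_scale:
        Hollow semi-axes as a fraction of the region's semi-axes, in (0, 1).
    fg_intensity, bg_intensity:
        Mean gray levels of foreground and background, in [0, 1].
    noise_sd:
        Standard deviation of additive Gaussian intensity noise.
    seed:
        Base RNG seed; pair ``index`` is drawn from stream (seed, index).
    """

    image_size: int = 64
    n_regions_choices: tuple[int, ...] = (1, 2)
    region_axis_range: tuple[float, float] = (6.0, 14.0)
    hollow_prob: float = 0.5
    hollow_scale: float = 0.4
    fg_intensity: float = 0.65
    bg_intensity: float = 0.25
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32 or self.image_size % 8:
            raise PhantomConfigError(
                f"image_size must be >= 32 and divisible by 8, got "
                f"{self.image_size}")
        choices = tuple(sorted(set(int(c) for c in self.n_regions_choices)))
        if not choices or not set(choices) <= {0, 1, 2}:
            raise PhantomConfigError(
                f"n_regions_choices must be a non-empty subset of {{0,1,2}}, "
                f"got {self.n_regions_choices}")
        object.__setattr__(self, "n_regions_choices", choices)
        lo, hi = self.region_axis_range
        if not (0 < lo <= hi):
            raise PhantomConfigError(
                f"region_axis_range must satisfy 0 < min <= max, got "
                f"{self.region_axis_range}")
        # two regions side by side: the bounding radius must fit in a half
        if 2 * hi >= self.image_size / 2:
            raise PhantomConfigError(
                f"max semi-axis {hi} too large for image_size "
                f"{self.image_size} (two regions must fit side by side)")
        if not 0 <= self.hollow_prob <= 1:
            raise PhantomConfigError("hollow_prob must lie in [0, 1]")
        if not 0 < self.hollow_scale < 1:
            raise PhantomConfigError("hollow_scale must lie in (0, 1)")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be non-negative")


@dataclasses.dataclass
class PhantomPair:
    """One synthetic slice with its ground-truth mask and provenance."""

    image: np.ndarray  # float32 in [0, 1], shape (H, W)
    mask: np.ndarray   # uint8 in {0, 1}, shape (H, W)
    meta: dict

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask must share dimensions")


def _ellipse_mask(size: int, center, axes, angle: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse on a ``size`` x ``size`` grid."""
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dc + sa * dr
    v = -sa * dc + ca * dr
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def generate_pair(config: PhantomConfig, index: int) -> PhantomPair:
    """Generate the phantom pair at position ``index`` of the dataset.

    Deterministic function of ``(config.seed, index)``.
    """
    if index < 0:
        raise ValueError("index must be non-negative")
    rng = np.random.default_rng((int(config.seed), int(index)))
    size = config.image_size
    lo, hi = config.region_axis_range

    n_regions = int(rng.choice(config.n_regions_choices))
    # left/right placement: with two regions one goes in each half
    sides = [0, 1] if n_regions == 2 else (
        [int(rng.integers(2))] if n_regions == 1 else [])

    mask = np.zeros((size, size), dtype=np.uint8)
    image = np.full((size, size), config.bg_intensity, dtype=np.float64)
    hollow_flags: list[bool] = []
    for side in sides:
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        angle = rng.uniform(0, np.pi)
        r_bound = max(a, b)
        half = size // 2
        cr = rng.uniform(r_bound, size - 1 - r_bound)
        cc_lo = side * half + r_bound
        cc_hi = (side + 1) * half - 1 - r_bound
        cc = rng.uniform(cc_lo, cc_hi) if cc_hi > cc_lo else (cc_lo + cc_hi) / 2
        region = _ellipse_mask(size, (cr, cc), (a, b), angle)
        hollow = bool(rng.random() < config.hollow_prob)
        hollow_flags.append(hollow)
        image[region] = config.fg_intensity
        mask[region] = 1
        if hollow:
            interior = _ellipse_mask(
                size, (cr, cc),
                (a * config.hollow_scale, b * config.hollow_scale), angle)
            image[interior] = config.bg_intensity
            mask[interior] = 0
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    meta = {
        "index": int(index),
        "seed": int(config.seed),
        "n_regions": n_regions,
        "hollow_flags": hollow_flags,
    }
    return PhantomPair(image=image, mask=mask, meta=meta)


def generate_dataset(config: PhantomConfig, n: int
                     ) -> tuple[list[PhantomPair], dict]:
    """Generate ``n`` pairs plus a manifest describing the run."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = [generate_pair(config, i) for i in range(n)]
    manifest = {
        "config": dataclasses.asdict(config),
        "n": n,
        "items": [p.meta for p in pairs],
    }
    return pairs, manifest


def save_dataset(pairs: Sequence[PhantomPair], manifest: dict,
                 out_dir: str | Path) -> None:
    """Write image/mask PNG pairs (8-bit gray; mask {0,255}) and a manifest."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(pairs):
        img8 = np.round(p.image * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out_dir / f"img_{i:05d}.png")
        Image.fromarray(p.mask * 255, mode="L").save(
            out_dir / f"mask_{i:05d}.png")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_dataset(in_dir: str | Path) -> tuple[list[PhantomPair], dict]:
    """Read a dataset written by :func:`save_dataset`."""
    from PIL import Image

    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    pairs = []
    for i in range(manifest["n"]):
        image = np.asarray(Image.open(in_dir / f"img_{i:05d}.png"),
                           dtype=np.float32) / 255.0
        mask = (np.asarray(Image.open(in_dir / f"mask_{i:05d}.png")) > 127
                ).astype(np.uint8)
        meta = manifest["items"][i] if i < len(manifest["items"]) else {}
        pairs.append(PhantomPair(image=image, mask=mask, meta=meta))
    return pairs, manifest
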