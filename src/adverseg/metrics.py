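"""Segmentation evaluation metrics.

Implements the standard overlap metrics (Dice similarity coefficient DSC,
volumetric overlap error VOE, pixel accuracy ACC, sensitivity SEN,
specificity SPE), the symmetric average surface distance (ASD) in physical
units, per-slice aggregation into a report with mean/std/max/min, and the
paired two-sided Wilcoxon signed-rank test for comparing two models on the
same slices.

Conventions for degenerate inputs (documented, and flagged in reports
rather than silently imputed):

* both masks empty -> DSC = 1.0 and VOE = 0 % (perfect agreement);
* ASD is undefined when either mask is empty -> reported as NaN, excluded
  from aggregation with a warning;
* SEN (resp. SPE) is undefined when the truth has no foreground (resp. no
  background) -> NaN for that slice.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

METRIC_NAMES = ("DSC", "VOE", "ASD", "ACC", "SEN", "SPE")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary, found values {vals[:10]}")
    return arr.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Pixelwise confusion counts for one binary (prediction, truth) pair."""
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2*TP / (2*TP + FP + FN); 1.0 when both
    masks are empty (documented convention)."""
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return 2 * c.tp / den


def voe(pred, truth) -> float:
    """Volumetric overlap error (1 - Jaccard) as a percentage; 0 % when both
    masks are empty."""
    c = pred if isinstance(pred, ConfusionCounts) else confusion(pred, truth)
    union = c.tp + c.fp + c.fn
    if union == 0:
        return 0.0
    return (1.0 - c.tp / union) * 100.0


@dataclasses.dataclass
class SurfaceSet:
    """Boundary pixels of a binary mask with their physical spacing."""

    coords: np.ndarray        # (n, 2) integer pixel coordinates (row, col)
    spacing: tuple[float, float]
    mask_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.coords)


def surface(mask, spacing=(1.0, 1.0), *, connectivity: int = 4) -> SurfaceSet:
    """Extract boundary pixels: foreground pixels with at least one
    background neighbour (4-connected by default, 8 by flag); the image
    border counts as background."""
    m = _check_binary(mask, "mask")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    interior = ndimage.binary_erosion(m, structure=struct, border_value=0)
    boundary = m & ~interior
    coords = np.argwhere(boundary)
    return SurfaceSet(coords=coords, spacing=(float(spacing[0]),
                                              float(spacing[1])),
                      mask_shape=m.shape)


def asd(pred, truth, spacing=(1.0, 1.0), *, connectivity: int = 4) -> float:
    """Symmetric average surface distance in physical units.

    NaN (undefined) when either mask is empty.
    """
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    sp = surface(p, spacing, connectivity=connectivity)
    st = surface(t, spacing, connectivity=connectivity)
    if len(sp) == 0 or len(st) == 0:
        warnings.warn("ASD undefined for an empty mask; reporting NaN",
                      stacklevel=2)
        return float("nan")
    d_p_to_t = _surface_distances(sp, st)
    d_t_to_p = _surface_distances(st, sp)
    return float((d_p_to_t.sum() + d_t_to_p.sum())
                 / (len(sp) + len(st)))


def _surface_distances(src: SurfaceSet, dst: SurfaceSet) -> np.ndarray:
    """Euclidean distance from each pixel of ``src`` to the nearest pixel of
    ``dst``, via a distance transform of the complement of ``dst``."""
    dst_mask = np.zeros(dst.mask_shape, dtype=bool)
    dst_mask[tuple(dst.coords.T)] = True
    dt = ndimage.distance_transform_edt(~dst_mask, sampling=dst.spacing)
    return dt[tuple(src.coords.T)]


def acc_sen_spe(c: ConfusionCounts) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity; NaN where the denominator of a
    metric is zero."""
    acc = (c.tp + c.tn) / c.total if c.total else float("nan")
    sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    return acc, sen, spe


def slice_metrics(pred, truth, spacing=(1.0, 1.0), *,
                  connectivity: int = 4) -> dict:
    """All six metrics for one binary prediction/truth pair."""
    c = confusion(pred, truth)
    a, se, sp = acc_sen_spe(c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surf_dist = asd(pred, truth, spacing, connectivity=connectivity)
    return {"DSC": dsc(c), "VOE": voe(c, None), "ASD": surf_dist,
            "ACC": a, "SEN": se, "SPE": sp}


@dataclasses.dataclass
class MetricReport:
    """Per-slice metric values plus mean/std/max/min aggregates."""

    per_slice: pd.DataFrame
    summary: pd.DataFrame
    flags: dict

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps float64 values bit-exact through a CSV round trip
        self.per_slice.to_csv(path, index_label="slice", float_format="%.17g")

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "n_slices": int(len(self.per_slice)),
            "flags": self.flags,
        }
        for name in METRIC_NAMES:
            row = self.summary.loc[name]
            d[name] = {k: (None if pd.isna(row[k]) else float(row[k]))
                       for k in ("mean", "std", "max", "min")}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d


def aggregate(per_slice: Sequence[dict] | pd.DataFrame) -> MetricReport:
    """Aggregate per-slice metric rows: mean, sample std, max, min over the
    non-missing values of each metric."""
    df = pd.DataFrame(per_slice)
    if df.empty:
        raise ValueError("aggregate needs at least one metric row")
    df = df.reindex(columns=list(METRIC_NAMES))
    flags = {}
    rows = {}
    for name in METRIC_NAMES:
        vals = df[name].dropna()
        n_missing = int(len(df) - len(vals))
        if n_missing:
            flags[name] = f"{n_missing} slice(s) undefined, excluded"
            if len(vals) == 0:
                warnings.warn(f"metric {name} undefined on every slice",
                              stacklevel=2)
        if len(vals):
            std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows[name] = {"mean": float(vals.mean()), "std": std,
                          "max": float(vals.max()), "min": float(vals.min())}
        else:
            rows[name] = {k: float("nan")
                          for k in ("mean", "std", "max", "min")}
    summary = pd.DataFrame(rows).T[["mean", "std", "max", "min"]]
    return MetricReport(per_slice=df, summary=summary, flags=flags)


def evaluate_masks(preds, truths, spacing=(1.0, 1.0), *,
                   connectivity: int = 4) -> MetricReport:
    """Per-slice metrics + aggregation for matched mask sequences."""
    if len(preds) != len(truths):
        raise ValueError("prediction and truth counts differ")
    rows = [slice_metrics(p, t, spacing, connectivity=connectivity)
            for p, t in zip(preds, truths)]
    return aggregate(rows)


def wilcoxon_paired(values_a, values_b) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns the signed-rank statistic ``W+ - W-`` (antisymmetric under
    swapping the samples) and the two-sided p-value. Zero differences are
    dropped; if every difference is zero the test is degenerate and
    ``(0.0, 1.0)`` is returned with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D with equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diff = a - b
    nz = diff[diff != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p-value = 1.0",
                      stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return w_plus - w_minus, float(res.pvalue)
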