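"""Reading CT volumes and turning them into 2-D training items.

Volumes arrive as NIfTI files (the layout of the public kidney-tumor
challenge data: an intensity volume plus an integer label volume with
0 = background, 1 = kidney, 2 = tumor). They are re-ordered to
(slice, row, column), windowed in Hounsfield units, scaled to [0, 1] and
split into per-slice image/mask pairs; the kidney label is collapsed to a
binary mask. The phantom PNG + manifest format is handled by
:mod:`adverseg.phantom`'s ``save_dataset`` / ``load_dataset``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .phantom import load_dataset, save_dataset  # re-exported  # noqa: F401

DEFAULT_HU_WINDOW = (-200.0, 300.0)


@dataclasses.dataclass(frozen=True)
class VolumeRecord:
    """One case: paths to the image and segmentation NIfTI volumes."""

    case_id: str
    image_path: Path
    segmentation_path: Path

    def __post_init__(self):
        object.__setattr__(self, "image_path", Path(self.image_path))
        object.__setattr__(self, "segmentation_path",
                           Path(self.segmentation_path))


def load_volume(record: VolumeRecord
                ) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Load one case; returns (intensity, labels, spacing).

    Arrays come back in (slice, row, column) order — the NIfTI (x, y, z)
    axes reversed — with labels preserved as integers; spacing is the voxel
    size in mm, matching the returned axis order.
    """
    import nibabel as nib

    img = nib.load(str(record.image_path))
    seg = nib.load(str(record.segmentation_path))
    vol = np.asarray(img.dataobj, dtype=np.float32)
    lab = np.asarray(seg.dataobj)
    lab = np.rint(lab).astype(np.int16)
    if vol.shape != lab.shape:
        raise ValueError(
            f"case {record.case_id}: image shape {vol.shape} != "
            f"segmentation shape {lab.shape}")
    sp_img = tuple(float(z) for z in img.header.get_zooms()[:3])
    sp_seg = tuple(float(z) for z in seg.header.get_zooms()[:3])
    if not np.allclose(sp_img, sp_seg):
        raise ValueError(
            f"case {record.case_id}: image spacing {sp_img} != "
            f"segmentation spacing {sp_seg}")
    vol = np.transpose(vol, (2, 1, 0))
    lab = np.transpose(lab, (2, 1, 0))
    spacing = sp_img[::-1]
    return vol, lab, spacing


@dataclasses.dataclass(frozen=True)
class SliceOptions:
    """How to turn a volume into 2-D training items.

    ``hu_window`` is mapped affinely to [0, 1] with clipping; labels outside
    {0, 1, 2} are rejected; ``merge_tumor`` counts tumor voxels as kidney;
    ``target_size`` (divisible by 8) resizes slices — bilinear for images,
    nearest-neighbour for masks; ``skip_blank`` drops slices whose mask is
    empty.
    """

    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    merge_tumor: bool = False
    target_size: int | None = None
    skip_blank: bool = False

    def __post_init__(self):
        lo, hi = self.hu_window
        if not lo < hi:
            raise ValueError("hu_window must satisfy lo < hi")
        if self.target_size is not None and (
                self.target_size < 8 or self.target_size % 8):
            raise ValueError("target_size must be divisible by 8")


def window_intensity(arr: np.ndarray, window=DEFAULT_HU_WINDOW) -> np.ndarray:
    """Affine map of the HU window to [0, 1] with clipping outside it."""
    lo, hi = window
    return np.clip((np.asarray(arr, dtype=np.float32) - lo) / (hi - lo),
                   0.0, 1.0)


def binarize_labels(lab: np.ndarray, merge_tumor: bool = False) -> np.ndarray:
    """Collapse {0: background, 1: kidney, 2: tumor} labels to a binary
    kidney mask; unknown values are an error."""
    lab = np.asarray(lab)
    unknown = np.setdiff1d(np.unique(lab), [0, 1, 2])
    if unknown.size:
        raise ValueError(f"unknown label values: {unknown.tolist()}")
    keep = (lab == 1) | (lab == 2) if merge_tumor else lab == 1
    return keep.astype(np.uint8)


def slice_dataset(volume: np.ndarray, labels: np.ndarray,
                  options: SliceOptions = SliceOptions()
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a (slice, row, column) volume into per-slice (image, mask)
    pairs, windowed, binarized and optionally resized."""
    from skimage.transform import resize

    volume = np.asarray(volume)
    if volume.shape != np.asarray(labels).shape:
        raise ValueError("volume and labels must share shape")
    mask3 = binarize_labels(labels, options.merge_tumor)
    img3 = window_intensity(volume, options.hu_window)
    items = []
    for img, msk in zip(img3, mask3):
        if options.skip_blank and not msk.any():
            continue
        if options.target_size is not None and img.shape != (
                options.target_size,) * 2:
            ts = (options.target_size, options.target_size)
            img = resize(img, ts, order=1, preserve_range=True,
                         anti_aliasing=True).astype(np.float32)
            msk = resize(msk, ts, order=0, preserve_range=True,
                         anti_aliasing=False).astype(np.uint8)
        items.append((img.astype(np.float32), msk))
    return items


def write_case_list(records, split_names, path) -> None:
    """Write a CSV case list assigning each volume record to a split."""
    import csv

    if len(records) != len(split_names):
        raise ValueError("one split name per record required")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "image_path", "segmentation_path",
                         "split"])
        for rec, split in zip(records, split_names):
            writer.writerow([rec.case_id, rec.image_path,
                             rec.segmentation_path, split])


def read_case_list(path) -> list[tuple[VolumeRecord, str]]:
    """Read a CSV case list back as (record, split) pairs."""
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((VolumeRecord(row["case_id"], row["image_path"],
                                     row["segmentation_path"]),
                        row["split"]))
    return out


def write_nifti_pair(image: np.ndarray, labels: np.ndarray,
                     spacing: tuple[float, ...], image_path, seg_path) -> None:
    """Write a (slice, row, column) volume pair as NIfTI files (test fixture
    helper; inverse of :func:`load_volume`'s axis convention)."""
    import nibabel as nib

    affine = np.diag(list(spacing[::-1]) + [1.0])
    img = nib.Nifti1Image(np.transpose(np.asarray(image), (2, 1, 0)), affine)
    img.header.set_zooms(spacing[::-1])
    nib.save(img, str(image_path))
    seg = nib.Nifti1Image(
        np.transpose(np.asarray(labels).astype(np.int16), (2, 1, 0)), affine)
    seg.header.set_zooms(spacing[::-1])
    nib.save(seg, str(seg_path))
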