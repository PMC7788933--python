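"""Dataset IO, normalization, augmentation, and the train/test split.

Datasets are directories with ``images/`` and ``masks/`` subdirectories of
PNG or TIFF files paired by filename stem.  Images are min-max scaled to
[0, 1] per image; masks are binarized at mid-intensity.  Augmentation is the
four exact pixel permutations -- horizontal flip, vertical flip, 90-degree
and 180-degree rotation -- applied jointly to image and mask; it expands a
sample into five and is applied to the training split only, after splitting,
so no transformed copy of a test image can leak into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "SegmentationSample",
    "AUGMENTATION_OPS",
    "load_dataset",
    "augment",
    "split",
    "write_mask_png",
]

IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class SegmentationSample:
    """A paired image (float in [0,1]) and binary mask, with an id."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"sample {self.id!r}: image shape {self.image.shape} != "
                f"mask shape {self.mask.shape}")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"sample {self.id!r}: mask is not binary")


def _to_gray(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr.astype(np.float64)


def _read_image(path: Path) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant image maps to all zeros."""
    arr = _to_gray(iio.imread(path), path)
    lo, hi = float(arr.min()), float(arr.max())
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def _read_mask(path: Path) -> np.ndarray:
    """Binarize at mid-intensity of the file's value range."""
    arr = _to_gray(iio.imread(path), path)
    hi = float(arr.max())
    return (arr > hi / 2).astype(np.uint8) if hi > 0 else np.zeros(arr.shape, np.uint8)


def load_dataset(directory) -> list[SegmentationSample]:
    """Load all paired samples under ``directory``, ordered by id."""
    root = Path(directory)
    img_dir, mask_dir = root / "images", root / "masks"
    for d in (img_dir, mask_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"missing directory {d}")

    def index(d: Path) -> dict[str, Path]:
        files = {}
        for p in sorted(d.iterdir()):
            if p.suffix.lower() in IMAGE_SUFFIXES:
                if p.stem in files:
                    raise ValueError(f"duplicate stem {p.stem!r} in {d}")
                files[p.stem] = p
        return files

    images, masks = index(img_dir), index(mask_dir)
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValueError(f"unpaired image/mask stems: {', '.join(orphans)}")
    return [SegmentationSample(_read_image(images[s]), _read_mask(masks[s]), s)
            for s in sorted(images)]


# Each op is an exact pixel permutation applied identically to image and mask;
# rot90 is counter-clockwise.
AUGMENTATION_OPS = {
    "hflip": lambda a: a[:, ::-1],
    "vflip": lambda a: a[::-1, :],
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
}


def augment(sample: SegmentationSample) -> list[SegmentationSample]:
    """The sample plus its four augmented variants (ids suffixed by op name)."""
    out = [sample]
    for name, op in AUGMENTATION_OPS.items():
        out.append(SegmentationSample(np.ascontiguousarray(op(sample.image)),
                                      np.ascontiguousarray(op(sample.mask)),
                                      f"{sample.id}__{name}"))
    return out


def split(samples: list[SegmentationSample], train_fraction: float = 0.8,
          seed: int = 0) -> tuple[list[SegmentationSample], list[SegmentationSample]]:
    """Seeded shuffle then split; train size is floor(fraction * N).

    Augment after splitting (training side only) to avoid leakage.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(samples))
    n_train = math.floor(train_fraction * len(samples))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as a single-channel 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))
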