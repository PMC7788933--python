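"""Seeded synthetic biomedical-image generator.

Two desk-scale task families emulate the structure of the evaluation data:

``organ_ct``
    One or a few smooth bright blobs (super-ellipses with low-frequency
    boundary deformation) on a textured darker background, echoing CT organ
    slices.  ``edge_blur_sigma`` optionally blurs the organ boundary in the
    *image only* -- the ground-truth mask is the exact pre-blur blob
    support, so boundary fuzziness can be varied with the truth held fixed.

``cell_em``
    A Voronoi tessellation of cell interiors separated by thin dark
    membranes, echoing electron-microscopy cell-boundary data; the mask
    marks membrane pixels.

Generation is bit-deterministic for a fixed seed, and images are min-max
normalized to span [0, 1] so an 8-bit PNG round trip through
:func:`write_dataset` / :func:`pyconvunet.datapipe.load_dataset` is lossless
up to quantization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .datapipe import SegmentationSample

__all__ = ["SynthConfig", "generate", "write_dataset"]

FAMILY_DEFAULT_OBJECTS = {"organ_ct": (1, 3), "cell_em": (18, 32)}


@dataclass(frozen=True)
class SynthConfig:
    family: str = "organ_ct"
    n_images: int = 8
    size: tuple[int, int] = (64, 64)
    n_objects: tuple[int, int] | None = None   # blobs (organ_ct) / cells (cell_em)
    fg_fraction_range: tuple[float, float] = (0.05, 0.4)
    edge_blur_sigma: float = 1.0
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILY_DEFAULT_OBJECTS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_images < 1:
            raise ValueError("n_images must be positive")
        h, w = self.size
        if h % 16 or w % 16 or h < 16 or w < 16:
            raise ValueError(f"size {h}x{w} must be divisible by 16")
        if self.edge_blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("edge_blur_sigma and noise_sd must be >= 0")
        lo, hi = self.objects_range
        if not (1 <= lo <= hi):
            raise ValueError("n_objects range must satisfy 1 <= lo <= hi")

    @property
    def objects_range(self) -> tuple[int, int]:
        return self.n_objects or FAMILY_DEFAULT_OBJECTS[self.family]


def _smooth_noise(rng, shape, sigma):
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    m = np.abs(z).max()
    return z / m if m > 0 else z


def _blob_support(rng, shape, n_blobs) -> np.ndarray:
    """Union of super-ellipse blobs with low-frequency boundary deformation."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w)
        a = rng.uniform(0.10, 0.28) * w
        b = rng.uniform(0.10, 0.28) * h
        theta = rng.uniform(0, np.pi)
        m = rng.uniform(1.6, 3.0)                     # super-ellipse exponent
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        r = (np.abs(u / a) ** m + np.abs(v / b) ** m) ** (1.0 / m)
        phi = np.arctan2(v, u)
        s = np.ones(shape)
        for k in range(1, 5):                         # low-frequency wobble
            s += rng.normal(0, 0.10 / k) * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
        mask |= r <= np.clip(s, 0.5, 1.5)
    return mask


def _organ_ct(rng, cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    h, w = cfg.size
    lo_n, hi_n = cfg.objects_range
    lo_f, hi_f = cfg.fg_fraction_range
    mask = None
    for _ in range(64):                               # deterministic retry loop
        n_blobs = int(rng.integers(lo_n, hi_n + 1))
        cand = _blob_support(rng, (h, w), n_blobs)
        frac = cand.mean()
        if lo_f <= frac <= hi_f:
            mask = cand
            break
    if mask is None:
        raise RuntimeError(
            f"could not draw a mask with foreground fraction in "
            f"[{lo_f}, {hi_f}] after 64 attempts; widen the range")
    background = 0.30 + 0.12 * _smooth_noise(rng, (h, w), max(h, w) / 10)
    foreground = 0.78 + 0.10 * _smooth_noise(rng, (h, w), max(h, w) / 16)
    noise = rng.normal(0, cfg.noise_sd, (h, w))
    # Truth is the pre-blur support; sigma touches only the image.
    soft = (ndimage.gaussian_filter(mask.astype(float), cfg.edge_blur_sigma)
            if cfg.edge_blur_sigma > 0 else mask.astype(float))
    img = background * (1 - soft) + foreground * soft + noise
    return img, mask.astype(np.uint8)


def _cell_em(rng, cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    h, w = cfg.size
    lo_n, hi_n = cfg.objects_range
    n_cells = int(rng.integers(lo_n, hi_n + 1))
    seeds = np.column_stack([rng.uniform(0, h, n_cells), rng.uniform(0, w, n_cells)])
    yy, xx = np.mgrid[0:h, 0:w]
    _, label = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
    label = label.reshape(h, w)
    membrane = np.zeros((h, w), dtype=bool)           # both sides of every edge
    membrane[:, :-1] |= label[:, :-1] != label[:, 1:]
    membrane[:, 1:] |= label[:, :-1] != label[:, 1:]
    membrane[:-1, :] |= label[:-1, :] != label[1:, :]
    membrane[1:, :] |= label[:-1, :] != label[1:, :]
    interiors = rng.uniform(0.60, 0.92, n_cells)[label]
    img = np.where(membrane, 0.12, interiors)
    img = ndimage.gaussian_filter(img, cfg.edge_blur_sigma * 0.5)
    img = img + rng.normal(0, cfg.noise_sd, (h, w))
    return img, membrane.astype(np.uint8)


def generate(config: SynthConfig) -> list[SegmentationSample]:
    """Generate ``config.n_images`` samples, bit-deterministic per seed."""
    make = _organ_ct if config.family == "organ_ct" else _cell_em
    children = np.random.SeedSequence(config.seed).spawn(config.n_images)
    samples = []
    for i, child in enumerate(children):
        img, mask = make(np.random.default_rng(child), config)
        lo, hi = float(img.min()), float(img.max())
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        samples.append(SegmentationSample(img, mask,
                                          f"{config.family}_{i:04d}"))
    return samples


def write_dataset(samples, directory) -> Path:
    """Write the datapipe layout: images/<id>.png + masks/<id>.png, 8-bit."""
    root = Path(directory)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s in samples:
        iio.imwrite(root / "images" / f"{s.id}.png",
                    np.round(s.image * 255).astype(np.uint8))
        iio.imwrite(root / "masks" / f"{s.id}.png",
                    (s.mask * 255).astype(np.uint8))
    return root
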