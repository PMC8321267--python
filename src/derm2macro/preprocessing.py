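"""Dataset containers, dark-corner cropping, resizing and split assignment.

Conventions used throughout the package:

* images are ``H x W x 3`` float arrays, RGB channel order, values in
  ``[0, 1]`` unless explicitly rescaled to ``[-1, 1]`` for the
  adversarial branch;
* masks are ``H x W`` boolean arrays;
* pixel coordinates are 0-based and crop boxes are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _skimage_resize

__all__ = ["ImageSample", "DomainDataset", "CropBox", "UncroppableError",
           "luminance", "detect_dark_corners", "crop", "resize_and_scale",
           "split_dataset", "DOMAINS", "SPLITS"]

DOMAINS = ("macro", "dermo", "trans_macro", "trans_dermo")
SPLITS = ("train", "val", "test")

#: Rec. 601 luma weights, the standard greyscale projection for RGB.
_LUMA = np.array([0.299, 0.587, 0.114])


class UncroppableError(ValueError):
    """Raised when no bright-cornered crop box of legal size exists."""


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an RGB image, same range as the input."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return image @ _LUMA


@dataclass
class ImageSample:
    """One RGB lesion image with its domain tag and optional mask."""

    pixels: np.ndarray
    domain: str
    id: str
    mask: np.ndarray | None = None
    split: str = "train"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError("mask shape must match pixel dimensions")


class DomainDataset:
    """Ordered collection of :class:`ImageSample` objects."""

    def __init__(self, samples: Iterable[ImageSample] = ()):
        self.samples: list[ImageSample] = list(samples)
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[ImageSample]:
        return iter(self.samples)

    def __getitem__(self, idx: int) -> ImageSample:
        return self.samples[idx]

    def subset(self, split: str) -> "DomainDataset":
        return DomainDataset([s for s in self.samples if s.split == split])

    # ------------------------------------------------------------------- I/O
    def save(self, directory: str | Path) -> Path:
        """Write images/masks as 8-bit PNG plus a manifest CSV."""
        directory = Path(directory)
        (directory / "images").mkdir(parents=True, exist_ok=True)
        (directory / "masks").mkdir(parents=True, exist_ok=True)
        rows = []
        for s in self.samples:
            img_path = directory / "images" / f"{s.id}.png"
            iio.imwrite(img_path, np.clip(np.round(s.pixels * 255), 0, 255)
                        .astype(np.uint8))
            mask_path = ""
            if s.mask is not None:
                mask_path = f"masks/{s.id}.png"
                iio.imwrite(directory / mask_path,
                            (s.mask.astype(np.uint8) * 255))
            row = {"id": s.id, "domain": s.domain, "split": s.split,
                   "image_path": f"images/{s.id}.png", "mask_path": mask_path}
            for k, v in sorted(s.meta.items()):
                row[f"meta_{k}"] = v
            rows.append(row)
        manifest = directory / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    @classmethod
    def load(cls, directory: str | Path) -> "DomainDataset":
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.csv",
                               keep_default_na=False)
        samples = []
        for _, row in manifest.iterrows():
            pixels = iio.imread(directory / row["image_path"])
            pixels = np.asarray(pixels, dtype=float)[..., :3] / 255.0
            mask = None
            if row.get("mask_path"):
                mask = iio.imread(directory / row["mask_path"]) > 127
            meta = {k[5:]: row[k] for k in manifest.columns
                    if k.startswith("meta_")}
            samples.append(ImageSample(pixels=pixels, domain=row["domain"],
                                       id=str(row["id"]), mask=mask,
                                       split=row["split"], meta=meta))
        return cls(samples)


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel box ``[top, top+height) x [left, left+width)``."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.top < 0 or self.left < 0:
            raise ValueError("box origin must be non-negative")
        if self.height < 32 or self.width < 32:
            raise ValueError("crop box must be at least 32 x 32")


def _corner_patches(image_lum: np.ndarray, box: CropBox,
                    corner_fraction: float) -> list[np.ndarray]:
    ph = max(1, int(round(box.height * corner_fraction)))
    pw = max(1, int(round(box.width * corner_fraction)))
    t, l_ = box.top, box.left
    b, r = box.top + box.height, box.left + box.width
    return [image_lum[t:t + ph, l_:l_ + pw], image_lum[t:t + ph, r - pw:r],
            image_lum[b - ph:b, l_:l_ + pw], image_lum[b - ph:b, r - pw:r]]


def detect_dark_corners(image: np.ndarray, darkness_threshold: float = 0.25,
                        corner_fraction: float = 0.15) -> CropBox:
    """Find the largest centered crop whose corner patches are all bright.

    Dermoscopes with a circular aperture leave dark corners on the
    image; those corners confuse a translator trained against clinical
    photographs, so they are cropped away.  The search shrinks a
    centered box symmetrically until the mean luminance of all four
    corner patches (each ``corner_fraction`` of the box side) reaches
    ``darkness_threshold``.

    Raises
    ------
    UncroppableError
        If no qualifying box of at least 32 x 32 pixels exists.
    """
    if not 0 < corner_fraction < 0.5:
        raise ValueError("corner_fraction must lie in (0, 0.5)")
    h, w = image.shape[:2]
    if h < 64 or w < 64:
        raise ValueError("image must be at least 64 x 64")
    lum = luminance(image)
    max_margin = (min(h, w) - 32) // 2
    for margin in range(0, max_margin + 1):
        box = CropBox(margin, margin, h - 2 * margin, w - 2 * margin)
        patches = _corner_patches(lum, box, corner_fraction)
        if all(p.mean() >= darkness_threshold for p in patches):
            return box
    raise UncroppableError(
        "no centered crop of at least 32 x 32 has bright corners")


def crop(image: np.ndarray, box: CropBox,
         mask: np.ndarray | None = None
         ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Crop an image (and optionally its mask) to ``box``."""
    h, w = image.shape[:2]
    if box.top + box.height > h or box.left + box.width > w:
        raise ValueError("crop box out of image bounds")
    sl = (slice(box.top, box.top + box.height),
          slice(box.left, box.left + box.width))
    cropped = image[sl]
    if mask is None:
        return cropped
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match image")
    return cropped, mask[sl]


def resize_and_scale(image: np.ndarray, target_size: int,
                     value_range: tuple[float, float] = (0.0, 1.0)
                     ) -> np.ndarray:
    """Bilinearly resize a ``[0, 1]`` RGB image and map its value range.

    ``value_range`` is ``(0, 1)`` for the segmentation branch (sigmoid
    head) and ``(-1, 1)`` for the adversarial branch (tanh output).
    """
    if target_size < 32:
        raise ValueError("target_size must be at least 32")
    lo, hi = value_range
    if (lo, hi) not in ((0.0, 1.0), (-1.0, 1.0)):
        raise ValueError("value_range must be (0, 1) or (-1, 1)")
    image = np.asarray(image, dtype=float)
    if image.shape[:2] != (target_size, target_size):
        image = _skimage_resize(image, (target_size, target_size),
                                order=1, mode="edge", anti_aliasing=False,
                                preserve_range=True)
    return image * (hi - lo) + lo


def resize_mask(mask: np.ndarray, target_size: int) -> np.ndarray:
    """Nearest-style resize for a boolean mask (bilinear then threshold)."""
    if mask.shape == (target_size, target_size):
        return mask.astype(bool)
    soft = _skimage_resize(mask.astype(float), (target_size, target_size),
                           order=1, mode="edge", anti_aliasing=False,
                           preserve_range=True)
    return soft >= 0.5


def split_dataset(dataset: DomainDataset | Sequence[ImageSample],
                  fractions: dict[str, float],
                  stratify_key: Callable[[ImageSample], object] | str | None = None,
                  seed: int = 0) -> DomainDataset:
    """Assign split tags by shuffling within strata and rounding counts.

    Counts per stratum follow the requested fractions with a
    largest-remainder rule, so 100 samples at 90/10 give exactly 90/10
    and 80 samples at 50/50 give 40/40.  A stratum smaller than the
    number of splits triggers a warning and best-effort assignment.
    """
    samples = list(dataset)
    names = list(fractions)
    fracs = np.array([fractions[n] for n in names], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if any(n not in SPLITS for n in names):
        raise ValueError(f"split names must be among {SPLITS}")

    if stratify_key is None:
        key = lambda s: None  # noqa: E731
    elif isinstance(stratify_key, str):
        key = lambda s: s.meta.get(stratify_key)  # noqa: E731
    else:
        key = stratify_key

    strata: dict[object, list[int]] = {}
    for i, s in enumerate(samples):
        strata.setdefault(key(s), []).append(i)

    rng = np.random.default_rng(seed)
    new_samples: list[ImageSample | None] = [None] * len(samples)
    for stratum in sorted(strata, key=repr):
        idx = np.array(strata[stratum])
        if len(idx) < len(names):
            warnings.warn(f"stratum {stratum!r} has fewer samples than splits;"
                          " best-effort assignment", stacklevel=2)
        order = rng.permutation(len(idx))
        counts = np.floor(fracs * len(idx)).astype(int)
        remainder = fracs * len(idx) - counts
        for j in np.argsort(-remainder, kind="stable")[:len(idx) - counts.sum()]:
            counts[j] += 1
        start = 0
        for name, cnt in zip(names, counts):
            for pos in order[start:start + cnt]:
                i = idx[pos]
                new_samples[i] = replace(samples[i], split=name)
            start += cnt
    return DomainDataset([s for s in new_samples if s is not None])
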