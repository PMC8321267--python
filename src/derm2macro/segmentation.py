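"""Lesion segmenter: a width-reduced mobile encoder-decoder network.

The encoder is an inverted-residual (MobileNet-style) backbone whose
channel widths are scaled by a width multiplier ``alpha`` (default
0.35), the decoder is an atrous spatial pyramid with low-level feature
fusion, and the head is a 1x1 convolution with a sigmoid producing a
per-pixel lesion probability.  Training minimizes the soft Dice loss
(1 - Dice) with Adam and a triangular cyclic learning rate, batch
size 4, and an internal 90/10 train/validation partition.

Images on this branch live in ``[0, 1]`` (sigmoid output range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv

from . import nn
from .preprocessing import DomainDataset, ImageSample, split_dataset

__all__ = ["SegModelSpec", "SegTrainConfig", "AugmentRecord", "Segmenter",
           "build_segmenter", "soft_dice_loss", "augment", "train_segmenter",
           "predict_mask", "make_divisible"]


def make_divisible(value: float, divisor: int = 8) -> int:
    """Round a scaled channel count to a hardware-friendly multiple."""
    new = max(divisor, int(value + divisor / 2) // divisor * divisor)
    if new < 0.9 * value:
        new += divisor
    return new


@dataclass(frozen=True)
class SegModelSpec:
    """Architecture of the segmenter.

    ``stage_config`` lists inverted-residual stages as ``(expansion,
    channels, repeats, stride)``; channels are multiplied by
    ``width_multiplier`` before rounding.  The default configuration is
    the full-scale network (512 px input, output stride 16, atrous
    rates 6/12/18); :meth:`desk_scale` returns a reduced preset that
    trains in minutes on a CPU.
    """

    width_multiplier: float = 0.35
    input_size: int = 512
    stem_channels: int = 32
    stage_config: tuple = ((1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2),
                           (6, 64, 4, 2), (6, 96, 3, 1))
    aspp_rates: tuple = (6, 12, 18)
    aspp_channels: int = 96
    low_level_stage: int = 1
    low_level_channels: int = 48
    decoder_channels: int = 96
    init_std: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.width_multiplier <= 1:
            raise ValueError("width multiplier must lie in (0, 1]")
        stride = 2 * int(np.prod([s for _, _, _, s in self.stage_config]))
        if self.input_size % stride != 0:
            raise ValueError(f"input_size must be divisible by the encoder "
                             f"output stride {stride}")

    @classmethod
    def desk_scale(cls, input_size: int = 64, alpha: float = 0.35
                   ) -> "SegModelSpec":
        """Reduced preset: output stride 8, small pyramid, 64 px input."""
        return cls(width_multiplier=alpha, input_size=input_size,
                   stem_channels=16,
                   stage_config=((1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 2, 2)),
                   aspp_rates=(1, 2, 4), aspp_channels=48,
                   low_level_channels=24, decoder_channels=48)

    def scaled_widths(self) -> list[int]:
        """Channel width of the stem and each backbone stage."""
        widths = [make_divisible(self.stem_channels * self.width_multiplier)]
        widths += [make_divisible(c * self.width_multiplier)
                   for _, c, _, _ in self.stage_config]
        return widths


@dataclass(frozen=True)
class SegTrainConfig:
    """Optimization protocol for the segmenter."""

    batch_size: int = 4
    epochs: int = 20
    val_fraction: float = 0.1
    base_lr: float = 1e-5
    max_lr: float = 1e-3
    lr_step_epochs: int = 4
    augment: bool = True
    smooth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")


class InvertedResidual(nn.Module):
    """Expand (1x1) - depthwise (3x3) - project (1x1), optional skip."""

    def __init__(self, cin: int, cout: int, stride: int, expansion: int,
                 init_std: float, rng: np.random.Generator):
        hidden = cin * expansion
        self.use_skip = stride == 1 and cin == cout
        self.expand = None
        if expansion != 1:
            self.expand = nn.Sequential(
                nn.Conv2d(cin, hidden, 1, init_std=init_std, rng=rng),
                nn.InstanceNorm2d(hidden), nn.ReLU())
        self.depthwise = nn.DepthwiseConv2d(hidden, 3, stride=stride,
                                            padding=1, init_std=init_std,
                                            rng=rng)
        self.dw_norm = nn.InstanceNorm2d(hidden)
        self.project = nn.Conv2d(hidden, cout, 1, init_std=init_std, rng=rng)
        self.proj_norm = nn.InstanceNorm2d(cout)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.expand(x) if self.expand is not None else x
        h = self.dw_norm(self.depthwise(h)).relu()
        h = self.proj_norm(self.project(h))
        return x + h if self.use_skip else h


class ASPP(nn.Module):
    """Atrous pyramid: 1x1, dilated 3x3 branches and global pooling."""

    def __init__(self, cin: int, cout: int, rates: Sequence[int],
                 init_std: float, rng: np.random.Generator):
        self.branch1 = nn.Sequential(
            nn.Conv2d(cin, cout, 1, init_std=init_std, rng=rng),
            nn.InstanceNorm2d(cout), nn.ReLU())
        self.atrous = [nn.Sequential(
            nn.Conv2d(cin, cout, 3, padding=r, dilation=r, init_std=init_std,
                      rng=rng),
            nn.InstanceNorm2d(cout), nn.ReLU()) for r in rates]
        self.pool_conv = nn.Conv2d(cin, cout, 1, init_std=init_std, rng=rng)
        self.project = nn.Sequential(
            nn.Conv2d((2 + len(rates)) * cout, cout, 1, init_std=init_std,
                      rng=rng),
            nn.InstanceNorm2d(cout), nn.ReLU())

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h, w = x.shape[2], x.shape[3]
        branches = [self.branch1(x)] + [b(x) for b in self.atrous]
        pooled = self.pool_conv(x.mean(axis=(2, 3), keepdims=True)).relu()
        ones = nn.Tensor(np.ones((1, 1, h, w)))
        branches.append(pooled * ones)
        return self.project(nn.concat(branches, axis=1))


class Segmenter(nn.Module):
    """Mobile encoder, atrous pyramid, low-level fusion, sigmoid head."""

    def __init__(self, spec: SegModelSpec, rng: np.random.Generator):
        self.spec = spec
        std = spec.init_std
        widths = spec.scaled_widths()
        self.stem = nn.Sequential(
            nn.Conv2d(3, widths[0], 3, stride=2, padding=1, init_std=std,
                      rng=rng),
            nn.InstanceNorm2d(widths[0]), nn.ReLU())
        self.stages: list[nn.Sequential] = []
        cin = widths[0]
        for (t, _, n, s), cout in zip(spec.stage_config, widths[1:]):
            blocks = []
            for i in range(n):
                blocks.append(InvertedResidual(cin, cout,
                                               s if i == 0 else 1, t, std, rng))
                cin = cout
            self.stages.append(nn.Sequential(*blocks))
        strides = [s for _, _, _, s in spec.stage_config]
        self.low_level_stride = 2 * int(np.prod(strides[:spec.low_level_stage + 1]))
        self.output_stride = 2 * int(np.prod(strides))
        self.aspp = ASPP(cin, spec.aspp_channels, spec.aspp_rates, std, rng)
        self.aspp_up = nn.Upsample2d(self.output_stride // self.low_level_stride)
        low_cin = widths[spec.low_level_stage + 1]
        self.low_project = nn.Sequential(
            nn.Conv2d(low_cin, spec.low_level_channels, 1, init_std=std,
                      rng=rng),
            nn.InstanceNorm2d(spec.low_level_channels), nn.ReLU())
        self.decoder = nn.Sequential(
            nn.Conv2d(spec.aspp_channels + spec.low_level_channels,
                      spec.decoder_channels, 3, padding=1, init_std=std,
                      rng=rng),
            nn.InstanceNorm2d(spec.decoder_channels), nn.ReLU())
        self.head = nn.Conv2d(spec.decoder_channels, 1, 1, init_std=std,
                              rng=rng)
        self.final_up = nn.Upsample2d(self.low_level_stride)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.stem(x)
        low = None
        for i, stage in enumerate(self.stages):
            h = stage(h)
            if i == self.spec.low_level_stage:
                low = h
        h = self.aspp_up(self.aspp(h))
        h = nn.concat([h, self.low_project(low)], axis=1)
        h = self.decoder(h)
        logits = self.final_up(self.head(h))
        return logits.sigmoid()


def build_segmenter(spec: SegModelSpec,
                    rng: np.random.Generator | None = None) -> Segmenter:
    """Build the segmenter; forward maps NxCxSxS in [0,1] to Nx1xSxS in (0,1)."""
    return Segmenter(spec, rng or np.random.default_rng(0))


def soft_dice_loss(pred: nn.Tensor | np.ndarray,
                   truth: nn.Tensor | np.ndarray,
                   smooth: float = 1.0) -> nn.Tensor:
    """``1 - (2 * sum(p * t) + s) / (sum(p) + sum(t) + s)`` over the batch."""
    if not isinstance(pred, nn.Tensor):
        pred = nn.Tensor(np.asarray(pred, dtype=float))
    truth_arr = truth.data if isinstance(truth, nn.Tensor) else \
        np.asarray(truth, dtype=float)
    truth_t = nn.Tensor(truth_arr.reshape(pred.shape))
    inter = (pred * truth_t).sum()
    denom = pred.sum() + truth_t.sum()
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


@dataclass(frozen=True)
class AugmentRecord:
    """Bookkeeping of the random draws used by :func:`augment`."""

    hflip: bool
    vflip: bool
    transpose: bool
    brightness: float
    contrast: float
    saturation: float
    hue: float
    noise_sigma: float


def augment(image: np.ndarray, mask: np.ndarray, rng_seed: int,
            return_record: bool = False):
    """Classic augmentation: random flips/transpose applied to image and
    mask alike; brightness/saturation/contrast/hue jitter and Gaussian
    noise applied to the image only.  The mask must be binary and stays
    binary."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    mask = mask.astype(bool)
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(rng_seed)
    rec = AugmentRecord(
        hflip=bool(rng.random() < 0.5),
        vflip=bool(rng.random() < 0.5),
        transpose=bool(rng.random() < 0.5),
        brightness=float(rng.uniform(-0.12, 0.12)),
        contrast=float(rng.uniform(0.85, 1.15)),
        saturation=float(rng.uniform(0.85, 1.15)),
        hue=float(rng.uniform(-0.04, 0.04)),
        noise_sigma=float(rng.uniform(0.0, 0.03)),
    )
    if rec.hflip:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rec.vflip:
        image, mask = image[::-1], mask[::-1]
    if rec.transpose:
        image, mask = image.transpose(1, 0, 2), mask.T

    hsv = rgb2hsv(np.clip(image, 0, 1))
    hsv[..., 0] = (hsv[..., 0] + rec.hue) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * rec.saturation, 0, 1)
    image = hsv2rgb(hsv)
    image = (image - image.mean()) * rec.contrast + image.mean() \
        + rec.brightness
    if rec.noise_sigma > 0:
        image = image + rng.normal(0, rec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)
    out = (np.ascontiguousarray(image), np.ascontiguousarray(mask))
    return (*out, rec) if return_record else out


def _to_batch(images: Sequence[np.ndarray]) -> nn.Tensor:
    return nn.Tensor(np.stack([im.transpose(2, 0, 1) for im in images])
                     .astype(np.float64))


def _hard_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    p = pred >= 0.5
    t = truth.astype(bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(p, t).sum() / denom


def train_segmenter(dataset: DomainDataset | Sequence[ImageSample],
                    config: SegTrainConfig, spec: SegModelSpec
                    ) -> tuple[Segmenter, pd.DataFrame]:
    """Train on masked ``[0, 1]`` samples; returns the best-val model.

    The dataset is split 90/10 internally (per ``val_fraction``); the
    per-epoch history records training loss, validation Dice and the
    cyclic learning rate.  The returned network carries the weights of
    the epoch with the highest validation Dice.
    """
    samples = list(dataset)
    if not samples:
        raise ValueError("dataset is empty")
    for s in samples:
        if s.mask is None:
            raise ValueError(f"sample {s.id} has no mask")
        if s.pixels.shape[:2] != (spec.input_size, spec.input_size):
            raise ValueError(f"sample {s.id} is not {spec.input_size} px")
        if s.pixels.min() < 0 or s.pixels.max() > 1:
            raise ValueError(f"sample {s.id} pixels outside [0, 1]")

    split = split_dataset(samples, {"train": 1.0 - config.val_fraction,
                                    "val": config.val_fraction},
                          seed=config.seed)
    train = [(s.pixels, s.mask) for s in split if s.split == "train"]
    val = [(s.pixels, s.mask) for s in split if s.split == "val"]
    if not train or not val:
        raise ValueError("dataset too small for a train/val partition")

    root = np.random.default_rng(config.seed)
    model = build_segmenter(spec, np.random.default_rng(root.integers(2**31)))
    opt = nn.Adam(model.parameters(), lr=config.base_lr, betas=(0.9, 0.999))
    sched = nn.CyclicLR(opt, base_lr=config.base_lr, max_lr=config.max_lr,
                        step_size=config.lr_step_epochs)
    shuffle_rng = np.random.default_rng(root.integers(2**31))
    aug_rng = np.random.default_rng(root.integers(2**31))

    rows = []
    best = {"dice": -1.0, "state": None, "epoch": -1}
    for epoch in range(config.epochs):
        lr = sched.current_lr()
        order = shuffle_rng.permutation(len(train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            images, masks = [], []
            for i in batch_idx:
                im, mk = train[i]
                if config.augment:
                    im, mk = augment(im, mk, int(aug_rng.integers(2**31)))
                images.append(im)
                masks.append(mk)
            model.zero_grad()
            pred = model(_to_batch(images))
            target = np.stack(masks).astype(float)[:, None]
            loss = soft_dice_loss(pred, target, config.smooth)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_dices = []
        for im, mk in val:
            prob = model(_to_batch([im])).data[0, 0]
            val_dices.append(_hard_dice(prob, mk))
        val_dice = float(np.mean(val_dices))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_dice": val_dice, "lr": lr})
        if val_dice > best["dice"]:
            best = {"dice": val_dice, "state": model.state_dict(),
                    "epoch": epoch}
        sched.step()
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best["epoch"]
    return model, history


def predict_mask(model: Segmenter, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Binarize the predicted probability map at ``threshold``."""
    prob = model(_to_batch([np.asarray(image, dtype=float)])).data[0, 0]
    return prob >= threshold
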