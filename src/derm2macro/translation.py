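"""Unpaired two-domain adversarial translator.

Two generators are trained jointly with two patch discriminators:
``G`` maps dermoscopic images to the macroscopic domain (its outputs
are called *TransMacro*) and ``F`` maps the other way (*TransDermo*).
``D_X`` discriminates real dermoscopic images from ``F`` outputs and
``D_Y`` real macroscopic images from ``G`` outputs.  The objective is

    L(G, F, D_X, D_Y) = L_GAN(F, D_X) + L_GAN(G, D_Y) + lambda * L_cyc(G, F)

with the cycle-consistency weight ``lambda`` defaulting to 10.  The
adversarial term is sigmoid cross-entropy of the discriminator patch
map against a constant target; the cycle term is the mean absolute
error of both round-trip reconstructions.  An optional identity-mapping
L1 term (weight 0 by default) is available for colour preservation.

Images on this branch live in ``[-1, 1]`` (tanh output range).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .preprocessing import DomainDataset, ImageSample

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "CycleGANConfig",
           "TranslationBundle", "ImagePool", "build_generator",
           "build_discriminator", "adversarial_loss", "cycle_loss",
           "total_loss", "train_cyclegan", "translate",
           "save_bundle", "load_bundle"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Encoder / residual transformer / decoder generator."""

    input_size: int = 128
    base_channels: int = 64
    n_residual_blocks: int = 12
    init_std: float = 0.02

    def __post_init__(self) -> None:
        if self.n_residual_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4 "
                             "(two stride-2 encoder stages)")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Patch discriminator: stacked 4x4 stride-2 convolutions."""

    base_channels: int = 64
    n_layers: int = 5
    init_std: float = 0.02

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("need at least two layers")


@dataclass(frozen=True)
class CycleGANConfig:
    """Training hyper-parameters plus the two network specifications."""

    generator: GeneratorSpec = GeneratorSpec()
    discriminator: DiscriminatorSpec = DiscriminatorSpec()
    lambda_cyc: float = 10.0
    identity_loss_weight: float = 0.0
    learning_rate: float = 2e-4
    beta1: float = 0.5
    max_epochs: int = 1000
    image_pool_size: int = 50
    early_stop_window: int = 10
    early_stop_tol: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_cyc <= 0:
            raise ValueError("lambda_cyc must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.identity_loss_weight < 0:
            raise ValueError("identity_loss_weight must be non-negative")


class Generator(nn.Module):
    """c7s1 encoder, stride-2 downsampling, residual blocks, upsampling."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        c = spec.base_channels
        std = spec.init_std
        self.spec = spec
        self.encoder = nn.Sequential(
            nn.Conv2d(3, c, 7, padding=3, pad_mode="reflect",
                      init_std=std, rng=rng),
            nn.InstanceNorm2d(c), nn.ReLU(),
            nn.Conv2d(c, 2 * c, 3, stride=2, padding=1, init_std=std, rng=rng),
            nn.InstanceNorm2d(2 * c), nn.ReLU(),
            nn.Conv2d(2 * c, 4 * c, 3, stride=2, padding=1, init_std=std,
                      rng=rng),
            nn.InstanceNorm2d(4 * c), nn.ReLU(),
        )
        self.residual_blocks = [nn.ResidualBlock(4 * c, rng=rng)
                                for _ in range(spec.n_residual_blocks)]
        self.decoder = nn.Sequential(
            nn.ConvTranspose2d(4 * c, 2 * c, 3, stride=2, padding=1,
                               output_padding=1, init_std=std, rng=rng),
            nn.InstanceNorm2d(2 * c), nn.ReLU(),
            nn.ConvTranspose2d(2 * c, c, 3, stride=2, padding=1,
                               output_padding=1, init_std=std, rng=rng),
            nn.InstanceNorm2d(c), nn.ReLU(),
        )
        self.head = nn.Conv2d(c, 3, 7, padding=3, pad_mode="reflect",
                              init_std=std, rng=rng)

    @property
    def n_residual_blocks(self) -> int:
        return len(self.residual_blocks)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.encoder(x)
        for block in self.residual_blocks:
            h = block(h)
        h = self.decoder(h)
        return self.head(h).tanh()


class PatchDiscriminator(nn.Module):
    """4x4/stride-2 convolution stack with a sigmoid patch-map output."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        c = spec.base_channels
        std = spec.init_std
        layers: list[nn.Module] = [
            nn.Conv2d(3, c, 4, stride=2, padding=1, init_std=std, rng=rng),
            nn.LeakyReLU(0.2)]
        cin = c
        for _ in range(spec.n_layers - 2):
            cout = min(cin * 2, 8 * c)
            layers += [nn.Conv2d(cin, cout, 4, stride=2, padding=1,
                                 init_std=std, rng=rng),
                       nn.InstanceNorm2d(cout), nn.LeakyReLU(0.2)]
            cin = cout
        layers += [nn.Conv2d(cin, 1, 4, stride=2, padding=1, init_std=std,
                             rng=rng), nn.Sigmoid()]
        self.net = nn.Sequential(*layers)

    @property
    def min_input(self) -> int:
        return 2 ** self.spec.n_layers

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        side = x.shape[2]
        if side < self.min_input:
            raise ValueError(f"input side {side} smaller than the "
                             f"discriminator receptive stride {self.min_input}")
        return self.net(x)


def build_generator(spec: GeneratorSpec,
                    rng: np.random.Generator | None = None) -> Generator:
    """Build a generator; weights ~ N(0, init_std^2), biases zero."""
    return Generator(spec, rng or np.random.default_rng(0))


def build_discriminator(spec: DiscriminatorSpec,
                        rng: np.random.Generator | None = None
                        ) -> PatchDiscriminator:
    return PatchDiscriminator(spec, rng or np.random.default_rng(0))


# -------------------------------------------------------------------- losses
def adversarial_loss(patch_probs: nn.Tensor | np.ndarray,
                     target: str) -> nn.Tensor:
    """Mean binary cross-entropy of a patch map against a constant target.

    ``target`` is ``"ones"`` (patches should look real) or ``"zeros"``.
    Probabilities are validated to lie in ``[0, 1]`` and clipped away
    from the endpoints before the logarithm.
    """
    if target not in ("ones", "zeros"):
        raise ValueError("target must be 'ones' or 'zeros'")
    probs = patch_probs if isinstance(patch_probs, nn.Tensor) \
        else nn.Tensor(np.asarray(patch_probs, dtype=float))
    if probs.data.min() < 0 or probs.data.max() > 1:
        raise ValueError("patch probabilities must lie in (0, 1)")
    p = probs.clip(1e-7, 1.0 - 1e-7)
    if target == "ones":
        return -(p.log().mean())
    return -((1.0 - p).log().mean())


def cycle_loss(x: nn.Tensor | np.ndarray, x_reconstructed: nn.Tensor | np.ndarray,
               y: nn.Tensor | np.ndarray, y_reconstructed: nn.Tensor | np.ndarray
               ) -> nn.Tensor:
    """Sum of forward and backward mean-absolute reconstruction errors."""
    def _wrap(t):
        return t if isinstance(t, nn.Tensor) else nn.Tensor(np.asarray(t, float))
    x, xr, y, yr = map(_wrap, (x, x_reconstructed, y, y_reconstructed))
    return (x - xr).abs().mean() + (y - yr).abs().mean()


def total_loss(l_gan_f, l_gan_g, l_cyc, lambda_cyc: float):
    """Full objective: both adversarial terms plus the weighted cycle term."""
    return l_gan_f + l_gan_g + lambda_cyc * l_cyc


class ImagePool:
    """Buffer of previously generated images for discriminator updates.

    With probability 1/2 a query swaps the incoming image against a
    stored one, which keeps the discriminators from chasing only the
    latest generator output.
    """

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, image: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return image
        if len(self.images) < self.size:
            self.images.append(image.copy())
            return image
        if self.rng.random() < 0.5:
            idx = int(self.rng.integers(len(self.images)))
            out = self.images[idx].copy()
            self.images[idx] = image.copy()
            return out
        return image


@dataclass
class TranslationBundle:
    """The four trained networks plus per-epoch loss history."""

    G: Generator
    F: Generator
    D_X: PatchDiscriminator
    D_Y: PatchDiscriminator
    history: pd.DataFrame
    config: CycleGANConfig


def _to_batch(image: np.ndarray) -> nn.Tensor:
    return nn.Tensor(np.ascontiguousarray(
        image.transpose(2, 0, 1)[None]).astype(np.float64))


def _check_gan_inputs(samples: Sequence[ImageSample], size: int) -> None:
    for s in samples:
        if s.pixels.shape[:2] != (size, size):
            raise ValueError(f"sample {s.id} is not {size}x{size}")
        if s.pixels.min() < -1.0 - 1e-6 or s.pixels.max() > 1.0 + 1e-6:
            raise ValueError(f"sample {s.id} pixels outside [-1, 1]")


def train_cyclegan(dermo: DomainDataset | Sequence[ImageSample],
                   macro: DomainDataset | Sequence[ImageSample],
                   config: CycleGANConfig) -> TranslationBundle:
    """Train the translator pair on unpaired ``[-1, 1]`` image sets.

    One optimizer step per image pair with batch size 1, Adam
    (beta1 = 0.5) at the configured learning rate, and an image pool
    for the discriminator updates.  Training stops at ``max_epochs`` or
    earlier when the windowed mean generator loss stabilizes (relative
    change below ``early_stop_tol`` between consecutive windows).
    """
    dermo_imgs = [s.pixels for s in dermo]
    macro_imgs = [s.pixels for s in macro]
    if not dermo_imgs or not macro_imgs:
        raise ValueError("both datasets must be non-empty")
    size = config.generator.input_size
    _check_gan_inputs(list(dermo), size)
    _check_gan_inputs(list(macro), size)

    root = np.random.default_rng(config.seed)
    G = build_generator(config.generator, np.random.default_rng(root.integers(2**31)))
    F = build_generator(config.generator, np.random.default_rng(root.integers(2**31)))
    D_X = build_discriminator(config.discriminator,
                              np.random.default_rng(root.integers(2**31)))
    D_Y = build_discriminator(config.discriminator,
                              np.random.default_rng(root.integers(2**31)))
    opt_g = nn.Adam(G.parameters() + F.parameters(), lr=config.learning_rate,
                    betas=(config.beta1, 0.999))
    opt_dx = nn.Adam(D_X.parameters(), lr=config.learning_rate,
                     betas=(config.beta1, 0.999))
    opt_dy = nn.Adam(D_Y.parameters(), lr=config.learning_rate,
                     betas=(config.beta1, 0.999))
    pool_x = ImagePool(config.image_pool_size,
                       np.random.default_rng(root.integers(2**31)))
    pool_y = ImagePool(config.image_pool_size,
                       np.random.default_rng(root.integers(2**31)))
    shuffle_rng = np.random.default_rng(root.integers(2**31))

    rows = []
    gen_totals: list[float] = []
    nets = {"G": G, "F": F, "D_X": D_X, "D_Y": D_Y}
    for epoch in range(config.max_epochs):
        order_x = shuffle_rng.permutation(len(dermo_imgs))
        order_y = shuffle_rng.permutation(len(macro_imgs))
        n_steps = min(len(order_x), len(order_y))
        acc = {k: 0.0 for k in ("loss_G_total", "loss_gan_G", "loss_gan_F",
                                "loss_cyc", "loss_D_X", "loss_D_Y")}
        for step in range(n_steps):
            x = _to_batch(dermo_imgs[order_x[step]])
            y = _to_batch(macro_imgs[order_y[step]])

            # --- generator update
            for net in nets.values():
                net.zero_grad()
            fake_y = G(x)
            fake_x = F(y)
            rec_x = F(fake_y)
            rec_y = G(fake_x)
            l_gan_g = adversarial_loss(D_Y(fake_y), "ones")
            l_gan_f = adversarial_loss(D_X(fake_x), "ones")
            l_cyc = cycle_loss(x.detach(), rec_x, y.detach(), rec_y)
            g_total = total_loss(l_gan_f, l_gan_g, l_cyc, config.lambda_cyc)
            if config.identity_loss_weight > 0:
                l_id = (G(y) - y.detach()).abs().mean() \
                    + (F(x) - x.detach()).abs().mean()
                g_total = g_total + config.identity_loss_weight * l_id
            g_total.backward()
            opt_g.step()

            # --- discriminator updates (fakes via the image pool)
            fx = nn.Tensor(pool_x.query(fake_x.data))
            fy = nn.Tensor(pool_y.query(fake_y.data))
            D_X.zero_grad()
            d_x_loss = 0.5 * (adversarial_loss(D_X(x), "ones")
                              + adversarial_loss(D_X(fx), "zeros"))
            d_x_loss.backward()
            opt_dx.step()
            D_Y.zero_grad()
            d_y_loss = 0.5 * (adversarial_loss(D_Y(y), "ones")
                              + adversarial_loss(D_Y(fy), "zeros"))
            d_y_loss.backward()
            opt_dy.step()

            values = {"loss_G_total": g_total.item(),
                      "loss_gan_G": l_gan_g.item(),
                      "loss_gan_F": l_gan_f.item(),
                      "loss_cyc": l_cyc.item(),
                      "loss_D_X": d_x_loss.item(),
                      "loss_D_Y": d_y_loss.item()}
            if not all(np.isfinite(v) for v in values.values()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: {values}")
            for k, v in values.items():
                acc[k] += v
        row = {"epoch": epoch}
        row.update({k: v / n_steps for k, v in acc.items()})
        rows.append(row)
        gen_totals.append(row["loss_G_total"])

        w = config.early_stop_window
        if len(gen_totals) >= 2 * w:
            recent = float(np.mean(gen_totals[-w:]))
            previous = float(np.mean(gen_totals[-2 * w:-w]))
            if abs(recent - previous) / max(abs(previous), 1e-12) \
                    < config.early_stop_tol:
                break

    return TranslationBundle(G=G, F=F, D_X=D_X, D_Y=D_Y,
                             history=pd.DataFrame(rows), config=config)


_DIRECTIONS = {
    "dermo_to_macro": ("G", "trans_macro"),
    "macro_to_dermo": ("F", "trans_dermo"),
}


def translate(bundle: TranslationBundle,
              samples: DomainDataset | Sequence[ImageSample],
              direction: str) -> list[ImageSample]:
    """Translate ``[-1, 1]`` samples across domains.

    ``direction`` is ``"dermo_to_macro"`` (outputs tagged
    ``trans_macro``) or ``"macro_to_dermo"`` (``trans_dermo``).  Masks
    are carried through unchanged: the translation is style-level and
    preserves lesion geometry.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(_DIRECTIONS)}")
    net_name, tag = _DIRECTIONS[direction]
    net = getattr(bundle, net_name)
    size = bundle.config.generator.input_size
    samples = list(samples)
    _check_gan_inputs(samples, size)
    out = []
    for s in samples:
        y = net(_to_batch(s.pixels))
        pixels = y.data[0].transpose(1, 2, 0)
        out.append(replace(s, pixels=pixels, domain=tag, id=f"trans_{s.id}"))
    return out


# --------------------------------------------------------------- checkpoints
def save_bundle(bundle: TranslationBundle, path: str | Path) -> Path:
    """Write the four networks + config + history to one zip checkpoint."""
    path = Path(path)
    meta = {"config": asdict(bundle.config)}

    def _write(zf: zipfile.ZipFile, name: str, payload: bytes | str) -> None:
        # fixed timestamp so identical training runs give identical files
        info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, payload)

    with zipfile.ZipFile(path, "w") as zf:
        _write(zf, "meta.json", json.dumps(meta, sort_keys=True))
        _write(zf, "history.csv", bundle.history.to_csv(index=False))
        for name in ("G", "F", "D_X", "D_Y"):
            for key, arr in getattr(bundle, name).state_dict().items():
                buf = io.BytesIO()
                np.save(buf, arr)
                _write(zf, f"{name}/{key}.npy", buf.getvalue())
    return path


def load_bundle(path: str | Path) -> TranslationBundle:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        cfg = meta["config"]
        cfg["generator"] = GeneratorSpec(**cfg["generator"])
        cfg["discriminator"] = DiscriminatorSpec(**cfg["discriminator"])
        config = CycleGANConfig(**cfg)
        history = pd.read_csv(io.BytesIO(zf.read("history.csv")))
        rng = np.random.default_rng(0)
        nets = {}
        entries = zf.namelist()
        for name in ("G", "F", "D_X", "D_Y"):
            builder = build_generator if name in ("G", "F") \
                else build_discriminator
            spec = config.generator if name in ("G", "F") \
                else config.discriminator
            net = builder(spec, rng)
            state = {e.split("/")[1][:-4]: np.load(io.BytesIO(zf.read(e)))
                     for e in entries if e.startswith(f"{name}/")}
            net.load_state_dict(state)
            nets[name] = net
    return TranslationBundle(history=history, config=config, **nets)
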