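"""Synthetic two-domain skin-lesion image generator.

Emulates, at desk scale, the structural difference between the two
acquisition domains used for lesion imaging:

* **dermoscopic** — uniform polarized illumination, pigment-network
  texture inside the lesion, diffuse borders, and optional acquisition
  artifacts (dark circular corners from the dermoscope aperture, a gel
  blur patch, ruler tick marks);
* **macroscopic** — clinical photograph look: warmer skin tone,
  specular glare highlights, shading that suggests lesion depth.

Dark corners / gel / ruler never appear in macroscopic renders and
glare / depth shading never appear in dermoscopic renders, so a simple
image statistic separates the domains and the translation task is
learnable even at smoke scale.  Every image is paired with an exact
ground-truth lesion mask, and generation is a pure function of the
configuration (seed included).

The lesion boundary is modeled as a star-convex radial function with a
few low-order harmonics; this is the simplest shape family that gives
diffuse-border-like variation while keeping the mask simply connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .preprocessing import DomainDataset, ImageSample, luminance, split_dataset

__all__ = ["LesionSpec", "ArtifactConfig", "SyntheticDatasetConfig",
           "generate_lesion_mask", "render_dermoscopic", "render_macroscopic",
           "generate_dataset", "DERMO_SKIN_TONE", "MACRO_SKIN_TONE"]

#: Cool, evenly lit tone seen under polarized dermoscope illumination.
DERMO_SKIN_TONE = (0.80, 0.66, 0.62)
#: Warmer ambient tone of a clinical photograph.
MACRO_SKIN_TONE = (0.85, 0.60, 0.45)


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and appearance of one lesion.

    ``boundary_harmonics`` is a list of ``(amplitude, phase)`` pairs;
    pair ``k`` perturbs the radius by ``amplitude * cos((k + 2) * theta
    + phase)`` (orders start at 2 so the centroid stays put).
    Amplitudes are absolute fractions of the image side, like
    ``radius``.
    """

    center: tuple[float, float] = (0.5, 0.5)
    radius: float = 0.25
    boundary_harmonics: Sequence[tuple[float, float]] = ()
    base_color: tuple[float, float, float] = (0.35, 0.22, 0.15)
    texture_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.05 < self.radius < 0.45:
            raise ValueError("radius must lie in (0.05, 0.45)")
        if not all(0 <= c <= 1 for c in self.center):
            raise ValueError("center must lie in the unit square")
        amp_sum = sum(abs(a) for a, _ in self.boundary_harmonics)
        if amp_sum >= self.radius:
            raise ValueError("harmonic amplitudes must sum below the radius")
        if not all(0 <= c <= 1 for c in self.base_color):
            raise ValueError("base_color must lie in [0, 1]")
        if self.texture_strength < 0:
            raise ValueError("texture_strength must be non-negative")

    @property
    def max_extent(self) -> float:
        return self.radius + sum(abs(a) for a, _ in self.boundary_harmonics)


@dataclass(frozen=True)
class ArtifactConfig:
    """Per-domain acquisition artifacts and background skin tone."""

    dark_corners: bool = False
    corner_darkness: float = 0.05
    gel: bool = False
    gel_blur: float = 2.5
    ruler: bool = False
    glare: bool = False
    glare_count: int = 1
    glare_intensity: float = 1.0
    depth_shading: bool = False
    depth_strength: float = 0.25
    skin_tone: tuple[float, float, float] = DERMO_SKIN_TONE

    def __post_init__(self) -> None:
        if not 0 <= self.corner_darkness < 0.1:
            raise ValueError("corner_darkness must lie in [0, 0.1)")
        if self.glare_count < 1:
            raise ValueError("glare_count must be at least 1")
        if not all(0 <= c <= 1 for c in self.skin_tone):
            raise ValueError("skin_tone must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Study conditions for one generated two-domain dataset."""

    n_images: int = 16
    image_size: int = 64
    seed: int = 0
    artifact_probabilities: dict = field(default_factory=lambda: {
        "dermo": {"dark_corners": 0.5, "gel": 0.2, "ruler": 0.2},
        "macro": {"glare": 0.7, "depth_shading": 0.5},
    })
    split_fractions: dict = field(default_factory=lambda: {
        "train": 0.8, "test": 0.2})

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be at least 1")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")


# --------------------------------------------------------------------- masks
def generate_lesion_mask(spec: LesionSpec, size: int,
                         rng_seed: int = 0) -> np.ndarray:
    """Rasterize the star-convex lesion boundary into a boolean mask.

    The result is a single 4-connected foreground component covering
    between 0.5% and 65% of the pixels; anything else indicates a
    degenerate specification and raises.
    """
    if size < 32:
        raise ValueError("size must be at least 32")
    cx, cy = spec.center
    ys, xs = np.meshgrid((np.arange(size) + 0.5) / size,
                         (np.arange(size) + 0.5) / size, indexing="ij")
    dx, dy = xs - cx, ys - cy
    theta = np.arctan2(dy, dx)
    r_bound = np.full_like(theta, spec.radius)
    for k, (amp, phase) in enumerate(spec.boundary_harmonics):
        r_bound = r_bound + amp * np.cos((k + 2) * theta + phase)
    mask = np.hypot(dx, dy) <= r_bound

    frac = mask.mean()
    if not 0.005 < frac < 0.65:
        raise ValueError(f"mask covers {frac:.1%} of pixels, outside (0.5%, 65%)")
    _, n_comp = ndimage.label(mask)  # default structure: 4-connectivity
    if n_comp != 1:
        raise ValueError("mask is not a single 4-connected component")
    return mask


# ------------------------------------------------------------------- renders
def _soft_mask(mask: np.ndarray, size: int) -> np.ndarray:
    return ndimage.gaussian_filter(mask.astype(float), sigma=max(0.6, size / 96))


def _render_base(mask: np.ndarray, spec: LesionSpec,
                 skin_tone: Sequence[float], rng_seed: int) -> np.ndarray:
    """Shared flat render: skin outside, lesion color + texture inside."""
    skin = np.asarray(skin_tone, dtype=float)
    base = np.asarray(spec.base_color, dtype=float)
    if not np.all(base < skin):
        raise ValueError("base_color must be darker than skin tone per channel")
    size = mask.shape[0]
    soft = _soft_mask(mask, size)
    image = skin[None, None, :] + soft[..., None] * (base - skin)[None, None, :]
    if spec.texture_strength > 0:
        rng = np.random.default_rng([rng_seed, 0])
        noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape),
                                        sigma=size / 32)
        noise = noise / (np.abs(noise).max() + 1e-12)
        # thresholded smoothed noise forms a mesh of thin lines: the
        # pigment-network cue typical of dermoscopy
        mesh = np.clip(1.0 - np.abs(noise) / 0.25, 0.0, 1.0)
        image = image - (spec.texture_strength * mesh * soft)[..., None] * 0.8
    return np.clip(image, 0.0, 1.0)


def _apply_dark_corners(image: np.ndarray, darkness: float) -> np.ndarray:
    size = image.shape[0]
    ys, xs = np.meshgrid(np.arange(size) + 0.5, np.arange(size) + 0.5,
                         indexing="ij")
    r = np.hypot(xs - size / 2, ys - size / 2) / (size / 2)
    t = np.clip((r - 0.95) / 0.20, 0.0, 1.0)
    factor = 1.0 - (1.0 - darkness) * (t * t * (3 - 2 * t))
    return image * factor[..., None]


def _apply_gel(image: np.ndarray, blur: float, rng: np.random.Generator
               ) -> np.ndarray:
    size = image.shape[0]
    cx = rng.uniform(0.3, 0.7) * size
    cy = rng.uniform(0.3, 0.7) * size
    radius = rng.uniform(0.15, 0.3) * size
    ys, xs = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    region = np.clip(1.0 - np.hypot(xs - cx, ys - cy) / radius, 0.0, 1.0)
    blurred = np.stack([ndimage.gaussian_filter(image[..., c], sigma=blur)
                        for c in range(3)], axis=-1)
    # a faint brightening goes with the blur, as with immersion gel
    blurred = np.clip(blurred + 0.02, 0.0, 1.0)
    return image + region[..., None] * (blurred - image)


def _apply_ruler(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    size = image.shape[0]
    out = image.copy()
    period = max(4, size // 12)
    offset = int(rng.integers(0, period))
    tick_h = max(2, size // 16)
    tick_w = max(1, size // 64)
    for x in range(offset, size, period):
        out[:tick_h, x:x + tick_w, :] *= 0.2
    return out


def _apply_glare(image: np.ndarray, spec: LesionSpec, count: int,
                 intensity: float, rng: np.random.Generator) -> np.ndarray:
    size = image.shape[0]
    sigma = 0.025 * size
    ring = float(np.clip(spec.max_extent + 0.10, 0.34, 0.44)) * size
    cx0, cy0 = spec.center[0] * size, spec.center[1] * size
    base_angle = rng.uniform(0, 2 * np.pi)
    ys, xs = np.meshgrid(np.arange(size) + 0.5, np.arange(size) + 0.5,
                         indexing="ij")
    out = image.copy()
    for k in range(count):
        angle = base_angle + 2 * np.pi * k / count \
            + rng.uniform(-0.1, 0.1) * 2 * np.pi / max(count, 2)
        gx = np.clip(cx0 + ring * np.cos(angle), 3 * sigma, size - 3 * sigma)
        gy = np.clip(cy0 + ring * np.sin(angle), 3 * sigma, size - 3 * sigma)
        blob = np.exp(-((xs - gx) ** 2 + (ys - gy) ** 2) / (2 * sigma ** 2))
        out = out + intensity * blob[..., None]
    return np.clip(out, 0.0, 1.0)


def _apply_depth_shading(image: np.ndarray, mask: np.ndarray,
                         spec: LesionSpec, strength: float,
                         rng: np.random.Generator) -> np.ndarray:
    size = image.shape[0]
    phi = rng.uniform(0, 2 * np.pi)
    ys, xs = np.meshgrid((np.arange(size) + 0.5) / size,
                         (np.arange(size) + 0.5) / size, indexing="ij")
    ramp = ((xs - spec.center[0]) * np.cos(phi)
            + (ys - spec.center[1]) * np.sin(phi)) / spec.radius
    soft = _soft_mask(mask, size)
    return np.clip(image + (strength * ramp * soft)[..., None], 0.0, 1.0)


def render_dermoscopic(mask: np.ndarray, spec: LesionSpec,
                       artifacts: ArtifactConfig, rng_seed: int = 0
                       ) -> np.ndarray:
    """Render the dermoscopic view of a lesion mask.

    Raises if the artifact configuration requests glare or depth
    shading, which belong to the macroscopic domain only.
    """
    if artifacts.glare or artifacts.depth_shading:
        raise ValueError("dermoscopic renders never use glare/depth_shading")
    image = _render_base(mask, spec, artifacts.skin_tone, rng_seed)
    if artifacts.gel:
        image = _apply_gel(image, artifacts.gel_blur,
                           np.random.default_rng([rng_seed, 1]))
    if artifacts.ruler:
        image = _apply_ruler(image, np.random.default_rng([rng_seed, 2]))
    if artifacts.dark_corners:
        image = _apply_dark_corners(image, artifacts.corner_darkness)
    return image


def render_macroscopic(mask: np.ndarray, spec: LesionSpec,
                       artifacts: ArtifactConfig, rng_seed: int = 0
                       ) -> np.ndarray:
    """Render the macroscopic (clinical photograph) view of a lesion.

    Raises if the artifact configuration requests dark corners, gel or
    ruler marks, which never appear in clinical photographs.
    """
    if artifacts.dark_corners or artifacts.gel or artifacts.ruler:
        raise ValueError(
            "macroscopic renders never use dark_corners/gel/ruler")
    image = _render_base(mask, spec, artifacts.skin_tone, rng_seed)
    if artifacts.depth_shading and artifacts.depth_strength != 0:
        image = _apply_depth_shading(image, mask, spec,
                                     artifacts.depth_strength,
                                     np.random.default_rng([rng_seed, 3]))
    if artifacts.glare:
        image = _apply_glare(image, spec, artifacts.glare_count,
                             artifacts.glare_intensity,
                             np.random.default_rng([rng_seed, 4]))
    return image


# ------------------------------------------------------------------- dataset
def _sample_spec(rng: np.random.Generator, dermoscopic: bool) -> LesionSpec:
    radius = rng.uniform(0.12, 0.30)
    n_harm = int(rng.integers(2, 5))
    amps = rng.uniform(0, 0.25 * radius / n_harm, size=n_harm)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    red = rng.uniform(0.25, 0.42)
    green = red * rng.uniform(0.55, 0.75)
    blue = green * rng.uniform(0.5, 0.8)
    texture = rng.uniform(0.10, 0.30) if dermoscopic else rng.uniform(0.0, 0.08)
    return LesionSpec(
        center=(rng.uniform(0.42, 0.58), rng.uniform(0.42, 0.58)),
        radius=radius,
        boundary_harmonics=tuple(zip(amps, phases)),
        base_color=(red, green, blue),
        texture_strength=texture,
    )


def _jitter_tone(tone: Sequence[float], rng: np.random.Generator
                 ) -> tuple[float, float, float]:
    jitter = rng.uniform(-0.03, 0.03, size=3)
    return tuple(float(np.clip(c + j, 0.0, 1.0)) for c, j in zip(tone, jitter))


def generate_dataset(config: SyntheticDatasetConfig
                     ) -> tuple[DomainDataset, DomainDataset]:
    """Generate the macroscopic and dermoscopic datasets.

    Returns ``(macro, dermo)``; each sample carries its ground-truth
    mask, split tag and artifact flags (in ``meta``).  The result is a
    pure function of the config, seed included.
    """
    probs = config.artifact_probabilities
    datasets = []
    for d_idx, domain in enumerate(("macro", "dermo")):
        dermoscopic = domain == "dermo"
        domain_probs = dict(probs.get(domain, {}))
        samples = []
        for i in range(config.n_images):
            rng = np.random.default_rng([config.seed, d_idx, i])
            spec = _sample_spec(rng, dermoscopic)
            render_seed = int(rng.integers(0, 2 ** 31))
            flags = {name: bool(rng.random() < p)
                     for name, p in sorted(domain_probs.items())}
            if dermoscopic:
                art = ArtifactConfig(
                    dark_corners=flags.get("dark_corners", False),
                    gel=flags.get("gel", False),
                    ruler=flags.get("ruler", False),
                    skin_tone=_jitter_tone(DERMO_SKIN_TONE, rng))
            else:
                art = ArtifactConfig(
                    glare=flags.get("glare", False),
                    glare_count=int(rng.integers(1, 3)),
                    depth_shading=flags.get("depth_shading", False),
                    skin_tone=_jitter_tone(MACRO_SKIN_TONE, rng))
            mask = generate_lesion_mask(spec, config.image_size)
            render = render_dermoscopic if dermoscopic else render_macroscopic
            pixels = render(mask, spec, art, render_seed)
            samples.append(ImageSample(
                pixels=pixels, domain=domain, id=f"{domain}_{i:04d}",
                mask=mask, meta=dict(flags)))
        dataset = split_dataset(samples, config.split_fractions,
                                seed=config.seed + d_idx)
        datasets.append(dataset)
    return datasets[0], datasets[1]


def corner_luminance_statistic(image: np.ndarray,
                               fraction: float = 0.12) -> float:
    """Mean corner-patch luminance; low values flag dermoscope corners."""
    lum = luminance(image)
    h, w = lum.shape
    ph, pw = max(1, int(h * fraction)), max(1, int(w * fraction))
    patches = [lum[:ph, :pw], lum[:ph, -pw:], lum[-ph:, :pw], lum[-ph:, -pw:]]
    return float(np.mean([p.mean() for p in patches]))
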