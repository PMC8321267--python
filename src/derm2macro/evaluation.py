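"""Quantitative evaluation: Fréchet distance between embedded image
sets, the Variation Ratio, and the lesion-segmentation metric suite.

The Fréchet distance treats each image set as a Gaussian ``N(mu,
Sigma)`` in an embedding space and computes

    d^2 = ||mu_a - mu_b||^2 + Tr(Sigma_a + Sigma_b - 2 (Sigma_a Sigma_b)^{1/2}).

The embedder is pluggable; the default is a fixed-seed random
convolutional projection, which is deterministic and needs no
pretrained weights.  Absolute distances under different embedders are
not comparable, but ratios of distances under one embedder are, which
is what the Variation Ratio

    VR = (reference - value) / reference

measures: VR > 0 means translation moved the two distributions closer
than the untranslated reference pair.

Segmentation quality is summarized by the six-metric suite used in
lesion-segmentation challenges: thresholded Jaccard (TJA; the
per-image Jaccard is zeroed when below 0.65 before averaging), Jaccard
(JA), Dice (DI), accuracy (AC), sensitivity (SE) and specificity (SP).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import numpy as np

from .nn.tensor import Tensor, conv2d, pad2d
from .preprocessing import ImageSample

__all__ = ["FeatureStats", "MetricsRecord", "RandomConvEmbedder",
           "embed_images", "frechet_distance", "variation_ratio",
           "round_half_away", "confusion_counts", "segmentation_metrics",
           "overlay", "normalized_error_rates", "compute_fid",
           "OVERLAY_COLORS"]


@dataclass(frozen=True)
class FeatureStats:
    """Sample mean and covariance of a set of embedded images."""

    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if self.n < 2:
            raise ValueError("need at least two samples (n >= 2)")
        if mean.ndim != 1 or cov.shape != (mean.size, mean.size):
            raise ValueError("mean length must equal covariance dimension")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


class RandomConvEmbedder:
    """Fixed-seed random convolutional projection of an RGB image.

    Three stride-2 convolution + ReLU stages followed by per-channel
    global mean and standard deviation pooling give a 64-dimensional
    embedding.  The weights are frozen at construction, so the
    embedding is deterministic and requires no pretrained model.
    Expects ``[0, 1]`` H x W x 3 input.
    """

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        widths = [(3, 8), (8, 16), (16, 32)]
        self.weights = [
            rng.normal(0, np.sqrt(2.0 / (cin * 9)), (cout, cin, 3, 3))
            for cin, cout in widths]
        self.dim = 64

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = Tensor(np.asarray(image, dtype=float).transpose(2, 0, 1)[None])
        for w in self.weights:
            x = conv2d(pad2d(x, 1), Tensor(w), stride=2).relu()
        feats = x.data[0]
        return np.concatenate([feats.mean(axis=(1, 2)),
                               feats.std(axis=(1, 2))])


def embed_images(samples: Iterable[ImageSample | np.ndarray],
                 embedder: Callable[[np.ndarray], np.ndarray]) -> FeatureStats:
    """Embed every image and fit a Gaussian (ddof-1 covariance)."""
    vectors = []
    for s in samples:
        image = s.pixels if isinstance(s, ImageSample) else np.asarray(s)
        vectors.append(np.asarray(embedder(image), dtype=float))
    if len(vectors) < 2:
        raise ValueError("need at least two images to estimate covariance")
    mat = np.stack(vectors)
    mean = mat.mean(axis=0)
    cov = np.cov(mat, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return FeatureStats(mean=mean, cov=cov, n=len(vectors))


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(a: FeatureStats, b: FeatureStats,
                     eps: float = 1e-6) -> float:
    """Fréchet distance between two Gaussian embedding summaries.

    The trace of the matrix square root is computed by
    eigendecomposition of the symmetrized product
    ``S_a^{1/2} Sigma_b S_a^{1/2}``; if that product has noticeably
    negative eigenvalues an ``eps``-jitter is added to both
    covariances and the computation retried.  Tiny negative results
    from roundoff are clamped to zero.
    """
    if a.mean.size != b.mean.size:
        raise ValueError("embedding dimensions differ")
    diff = a.mean - b.mean
    cov_a, cov_b = a.cov, b.cov
    sqrt_a = _psd_sqrt(cov_a)
    prod = sqrt_a @ cov_b @ sqrt_a
    vals = np.linalg.eigvalsh(prod)
    scale = max(np.abs(vals).max(), 1.0)
    if vals.min() < -1e-9 * scale:
        jitter = eps * np.eye(cov_a.shape[0])
        sqrt_a = _psd_sqrt(cov_a + jitter)
        prod = sqrt_a @ (cov_b + jitter) @ sqrt_a
        vals = np.linalg.eigvalsh(prod)
    tr_sqrt = np.sqrt(np.clip(vals, 0.0, None)).sum()
    d2 = diff @ diff + np.trace(cov_a) + np.trace(cov_b) - 2.0 * tr_sqrt
    return float(max(d2, 0.0))


def variation_ratio(reference: float, value: float) -> float:
    """``(reference - value) / reference``; positive when the
    translated pair is closer than the untranslated reference pair."""
    if reference <= 0:
        raise ValueError("reference distance must be positive")
    return (reference - value) / reference


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round with halves going away from zero (reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def compute_fid(images_a: Iterable, images_b: Iterable,
                embedder: Callable[[np.ndarray], np.ndarray] | None = None
                ) -> float:
    """Convenience wrapper: embed both sets and take the distance."""
    embedder = embedder or RandomConvEmbedder()
    return frechet_distance(embed_images(images_a, embedder),
                            embed_images(images_b, embedder))


# ------------------------------------------------------------- segmentation
def confusion_counts(pred: np.ndarray, truth: np.ndarray
                     ) -> tuple[int, int, int, int]:
    """Pixelwise ``(TP, FP, FN, TN)`` for two binary masks."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share a shape")
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(np.logical_and(pred, ~truth).sum())
    fn = int(np.logical_and(~pred, truth).sum())
    tn = int(np.logical_and(~pred, ~truth).sum())
    return tp, fp, fn, tn


def _safe_ratio(num: int, den: int, empty_value: float = 1.0) -> float:
    """Ratio with the convention that 0/0 counts as perfect agreement."""
    return num / den if den else empty_value


@dataclass(frozen=True)
class MetricsRecord:
    """Per-image Jaccard values plus the six aggregate metrics.

    All aggregates are means of per-image values in ``[0, 1]``.
    ``counts`` holds the pooled pixel confusion counts and
    ``norm_fp`` / ``norm_fn`` the mean per-image false-positive and
    false-negative pixel counts normalized by the ground-truth
    foreground area.
    """

    per_image_ja: tuple
    tja: float
    ja: float
    di: float
    ac: float
    se: float
    sp: float
    counts: tuple[int, int, int, int]
    norm_fp: float
    norm_fn: float
    tja_threshold: float


def segmentation_metrics(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                         tja_threshold: float = 0.65) -> MetricsRecord:
    """Compute the six-metric suite over ``(pred, truth)`` mask pairs.

    Per image: ``JA = TP/(TP+FP+FN)``, ``DI = 2TP/(2TP+FP+FN)``,
    ``AC = (TP+TN)/N``, ``SE = TP/(TP+FN)``, ``SP = TN/(TN+FP)``; a
    pair with empty prediction *and* empty truth counts as perfect
    (``JA = DI = SE = 1``).  TJA zeroes each per-image Jaccard below
    ``tja_threshold`` before averaging, so ``TJA <= JA`` always.
    """
    if not pairs:
        raise ValueError("no mask pairs given")
    jas, dis, acs, ses, sps, tjas = [], [], [], [], [], []
    pooled = np.zeros(4, dtype=np.int64)
    norm_fp, norm_fn = [], []
    for pred, truth in pairs:
        tp, fp, fn, tn = confusion_counts(pred, truth)
        pooled += (tp, fp, fn, tn)
        ja = _safe_ratio(tp, tp + fp + fn)
        jas.append(ja)
        tjas.append(ja if ja >= tja_threshold else 0.0)
        dis.append(_safe_ratio(2 * tp, 2 * tp + fp + fn))
        acs.append((tp + tn) / (tp + fp + fn + tn))
        ses.append(_safe_ratio(tp, tp + fn))
        sps.append(_safe_ratio(tn, tn + fp))
        fg = tp + fn
        total = tp + fp + fn + tn
        norm_fp.append(fp / fg if fg else fp / total)
        norm_fn.append(fn / fg if fg else 0.0)
    return MetricsRecord(
        per_image_ja=tuple(jas),
        tja=float(np.mean(tjas)), ja=float(np.mean(jas)),
        di=float(np.mean(dis)), ac=float(np.mean(acs)),
        se=float(np.mean(ses)), sp=float(np.mean(sps)),
        counts=tuple(int(c) for c in pooled),
        norm_fp=float(np.mean(norm_fp)), norm_fn=float(np.mean(norm_fn)),
        tja_threshold=tja_threshold)


#: Overlay color table: TP yellow, FP red, FN green, TN black.
OVERLAY_COLORS = {
    "tp": (255, 255, 0),
    "fp": (255, 0, 0),
    "fn": (0, 255, 0),
    "tn": (0, 0, 0),
}


def overlay(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Render the prediction/truth comparison as an 8-bit RGB image.

    Yellow marks true positives, red over-segmentation (false
    positives), green under-segmentation (false negatives) and black
    the agreed background.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share a shape")
    out = np.zeros(pred.shape + (3,), dtype=np.uint8)
    out[pred & truth] = OVERLAY_COLORS["tp"]
    out[pred & ~truth] = OVERLAY_COLORS["fp"]
    out[~pred & truth] = OVERLAY_COLORS["fn"]
    return out


def normalized_error_rates(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                           normalizer: str = "foreground"
                           ) -> tuple[float, float]:
    """Mean per-image FP and FN pixel counts, normalized.

    ``normalizer='foreground'`` divides by each image's ground-truth
    foreground area (an empty truth falls back to the total pixel
    count for FP and contributes 0 FN); ``'total'`` divides by the
    image size.
    """
    if normalizer not in ("foreground", "total"):
        raise ValueError("normalizer must be 'foreground' or 'total'")
    fps, fns = [], []
    for pred, truth in pairs:
        tp, fp, fn, tn = confusion_counts(pred, truth)
        total = tp + fp + fn + tn
        if normalizer == "total":
            den_fp = den_fn = total
        else:
            fg = tp + fn
            den_fp = fg if fg else total
            den_fn = fg if fg else 1
        fps.append(fp / den_fp)
        fns.append(fn / den_fn)
    if not fps:
        raise ValueError("no mask pairs given")
    return float(np.mean(fps)), float(np.mean(fns))
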