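"""Restoration quality metrics and the paired evaluation protocol.

Metrics are computed on normalized [0, 1] images with ``max_value = 1.0``.
The protocol mirrors how inpainting quality is reported: one metric triple
(PSNR, SSIM, FID) for originals-vs-masked (how much the artifact destroys)
and one for originals-vs-restored (how much the model recovers), each over
the same paired collection.

FID needs a deep embedding; the embedder is pluggable for the same reason
as the perceptual extractor — the default is a bundled fixed-seed CNN, and
any Inception-style embedder can be substituted where its weights exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.ndimage import gaussian_filter

from .autograd import Tensor, no_grad
from .losses import TinyFeatureExtractor
from .screening import GrayImage

#: reported PSNR for a zero-MSE pair (identical images)
PSNR_CAP_DB = 100.0


def psnr(a: GrayImage | np.ndarray, b: GrayImage | np.ndarray,
         max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(max^2 / MSE), in dB."""
    x = a.data if isinstance(a, GrayImage) else np.asarray(a, dtype=np.float64)
    y = b.data if isinstance(b, GrayImage) else np.asarray(b, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((x.astype(np.float64) - y.astype(np.float64)) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, float(10.0 * np.log10(max_value ** 2 / mse)))


def ssim(a: GrayImage | np.ndarray, b: GrayImage | np.ndarray,
         max_value: float = 1.0, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with the standard 11-tap Gaussian window.

    Follows the canonical definition: Gaussian-weighted local means and
    (population) covariances with sigma 1.5 truncated at 3.5 sigma, constants
    C1=(K1 R)^2, C2=(K2 R)^2, and a border strip of the window radius
    excluded from the mean.
    """
    x = a.data if isinstance(a, GrayImage) else np.asarray(a)
    y = b.data if isinstance(b, GrayImage) else np.asarray(b)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    truncate = 3.5
    r = int(truncate * sigma + 0.5)
    win = 2 * r + 1
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} window")
    x = x.astype(np.float64)
    y = y.astype(np.float64)
    args = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ux = gaussian_filter(x, **args)
    uy = gaussian_filter(y, **args)
    uxx = gaussian_filter(x * x, **args)
    uyy = gaussian_filter(y * y, **args)
    uxy = gaussian_filter(x * y, **args)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * max_value) ** 2
    c2 = (k2 * max_value) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def frechet_distance(mu1: np.ndarray, cov1: np.ndarray,
                     mu2: np.ndarray, cov2: np.ndarray) -> float:
    """||mu1-mu2||^2 + tr(S1 + S2 - 2 (S1 S2)^{1/2}).

    The matrix square root is stabilized against the small negative
    eigenvalues that finite-sample covariances produce.
    """
    mu1, mu2 = np.atleast_1d(mu1), np.atleast_1d(mu2)
    cov1, cov2 = np.atleast_2d(cov1), np.atleast_2d(cov2)
    if mu1.shape != mu2.shape or cov1.shape != cov2.shape:
        raise ValueError("dimension mismatch")
    diff = mu1 - mu2
    prod = cov1 @ cov2
    sqrtm, _ = scipy.linalg.sqrtm(prod, disp=False)
    if np.iscomplexobj(sqrtm):
        sqrtm = sqrtm.real
    return float(diff @ diff + np.trace(cov1) + np.trace(cov2)
                 - 2.0 * np.trace(sqrtm))


class TinyEmbedder:
    """Deterministic image embedder for FID: fixed-seed CNN activations,
    globally average-pooled and concatenated across layers."""

    def __init__(self, seed: int = 4321):
        self.net = TinyFeatureExtractor(seed=seed).eval()

    @property
    def dim(self) -> int:
        return sum(c.out_ch for c in self.net.convs)

    def embed(self, images: Sequence[GrayImage | np.ndarray]) -> np.ndarray:
        arrays = [im.data if isinstance(im, GrayImage) else np.asarray(im)
                  for im in images]
        batch = np.stack(arrays)[:, None].astype(np.float32)
        with no_grad():
            feats = self.net(Tensor(batch))
        pooled = [f.data.mean(axis=(2, 3)) for f in feats]
        return np.concatenate(pooled, axis=1).astype(np.float64)


def _fit_gaussian(emb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = emb.mean(axis=0)
    n, d = emb.shape
    if n <= 1:
        return mu, np.zeros((d, d))
    cov = np.cov(emb, rowvar=False)
    if n < d + 2:
        # shrinkage toward the diagonal keeps the covariance well-posed
        # for small sets; logged rather than silent
        import logging
        logging.getLogger(__name__).info(
            "set size %d < embedding dim %d: applying diagonal shrinkage", n, d)
        cov = 0.9 * cov + 0.1 * np.diag(np.diag(cov) + 1e-6)
    return mu, np.atleast_2d(cov)


def fid(set_a: Sequence, set_b: Sequence,
        embedder: TinyEmbedder | None = None) -> float:
    """Frechet distance between Gaussians fitted to deep embeddings."""
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both image sets must be non-empty")
    embedder = embedder or TinyEmbedder()
    ea = embedder.embed(set_a)
    eb = embedder.embed(set_b)
    return frechet_distance(*_fit_gaussian(ea), *_fit_gaussian(eb))


@dataclass
class MetricsReport:
    group: str        # "mask" or "restoration"
    psnr_db: float    # mean over pairs
    ssim: float       # mean over pairs
    fid: float
    n_pairs: int


def evaluate_protocol(originals: Sequence[GrayImage],
                      masked: Sequence[GrayImage],
                      restored: Sequence[GrayImage],
                      embedder: TinyEmbedder | None = None,
                      out_csv: str | Path | None = None
                      ) -> tuple[MetricsReport, MetricsReport]:
    """Paired mask-group vs restoration-group evaluation.

    Both groups compare against the same originals; per-pair PSNR/SSIM are
    averaged, FID is computed set-to-set.
    """
    if not (len(originals) == len(masked) == len(restored)):
        raise ValueError("collections must be aligned")
    if len(originals) == 0:
        raise ValueError("need at least one image pair")
    embedder = embedder or TinyEmbedder()

    def group(label: str, others: Sequence[GrayImage]) -> MetricsReport:
        return MetricsReport(
            group=label,
            psnr_db=float(np.mean([psnr(o, m)
                                   for o, m in zip(originals, others)])),
            ssim=float(np.mean([ssim(o, m)
                                for o, m in zip(originals, others)])),
            fid=fid(originals, others, embedder),
            n_pairs=len(originals))

    reports = (group("mask", masked), group("restoration", restored))
    if out_csv:
        import pandas as pd
        pd.DataFrame([r.__dict__ for r in reports]).to_csv(out_csv, index=False)
    return reports
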