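"""Loss terms and the two composite training objectives.

Stage 1 (edge network): non-saturating sigmoid GAN loss plus a
feature-matching term over the discriminator's intermediate activations,

    L_G1 = lambda_adv1 * L_adv1 + lambda_FM * L_FM,   lambda_adv1=1, lambda_FM=10.

Stage 2 (content network): weighted sum of pixel L1, adversarial,
perceptual and style (Gram-matrix) terms,

    L_G2 = lambda_l1 * L_l1 + lambda_adv2 * L_adv2 + lambda_p * L_perc + lambda_s * L_style.

The perceptual/style feature extractor is pluggable; the package default is
a bundled fixed-seed CNN so nothing is downloaded.  All losses are plain
engine scalars, so gradients flow into whichever inputs require them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Conv2d, Module, Tensor, concat

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class LossWeights:
    """The lambda multipliers of the two objectives (all dimensionless).

    The edge-stage pair is fixed by the method (adv 1, FM 10); the content
    weights follow the EdgeConnect lineage and are freely overridable.
    """

    lambda_adv1: float = 1.0
    lambda_fm: float = 10.0
    lambda_l1: float = 1.0
    lambda_adv2: float = 0.1
    lambda_perc: float = 0.1
    lambda_style: float = 250.0

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be nonnegative")


def _clamped(scores: Tensor) -> Tensor:
    lo, hi = scores.data.min(), scores.data.max()
    if lo < 0.0 or hi > 1.0:
        logger.warning("discriminator scores outside (0,1): [%g, %g]", lo, hi)
    return scores.clamp(_EPS, 1.0 - _EPS)


def adversarial_loss(d_real: Tensor | None, d_fake: Tensor,
                     role: str) -> Tensor:
    """Sigmoid-GAN binary cross-entropy, averaged over the score map.

    ``discriminator``: -[E log D(real) + E log(1 - D(fake))].
    ``generator``: the non-saturating -E log D(fake).
    """
    d_fake = _clamped(d_fake)
    if role == "discriminator":
        if d_real is None:
            raise ValueError("discriminator role needs real scores")
        d_real = _clamped(d_real)
        return -(d_real.log().mean() + (1.0 - d_fake).log().mean())
    if role == "generator":
        return -d_fake.log().mean()
    raise ValueError(f"unknown role {role!r}")


def feature_matching_loss(real_feats: list[Tensor],
                          fake_feats: list[Tensor]) -> Tensor:
    """sum_i (1/N_i) ||D^i(real) - D^i(fake)||_1 over discriminator layers.

    Real activations are detached: the term trains the generator only.
    """
    if len(real_feats) != len(fake_feats):
        raise ValueError("feature lists differ in length")
    total = Tensor(0.0)
    for r, f in zip(real_feats, fake_feats):
        if r.shape != f.shape:
            raise ValueError("feature shapes differ")
        total = total + (r.detach() - f).abs().mean()
    return total


def l1_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Mean absolute pixel difference."""
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    return (pred - target).abs().mean()


class TinyFeatureExtractor(Module):
    """Bundled fixed-seed CNN used for perceptual/style losses and FID.

    Three strided 3x3 convolution + ReLU stages; deterministic for a given
    seed, no pretrained weights required.  Any deep feature stack with the
    same interface (``__call__ -> list of activation maps``) can replace it,
    e.g. an ImageNet VGG-19 where such weights are available.
    """

    in_channels = 1

    def __init__(self, seed: int = 1234, widths: tuple[int, ...] = (8, 16, 16)):
        super().__init__()
        rng = np.random.default_rng(seed)
        chans = [self.in_channels, *widths]
        self.convs = []
        for i, (ci, co) in enumerate(zip(chans[:-1], chans[1:])):
            conv = Conv2d(ci, co, 3, stride=2, pad=1, act="relu", rng=rng)
            self.convs.append(conv)
            self._modules[f"conv{i}"] = conv
        self.n_layers = len(self.convs)

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.ndim != 4:
            raise ValueError("expected (N, C, H, W) input")
        if x.shape[1] != self.in_channels:
            if x.shape[1] == 1:   # replicate grayscale to expected channels
                x = concat([x] * self.in_channels, axis=1)
            else:
                raise ValueError("channel mismatch for extractor")
        feats = []
        for conv in self.convs:
            x = conv(x)
            feats.append(x)
        return feats


def perceptual_loss(extractor: Module, pred: Tensor, target: Tensor) -> Tensor:
    """sum_i (1/N_i) ||phi_i(target) - phi_i(pred)||_1 over extractor layers."""
    if extractor is None:
        raise ValueError("feature extractor is not initialized")
    pf = extractor(pred)
    tf = extractor(target.detach())
    total = Tensor(0.0)
    for p, t in zip(pf, tf):
        total = total + (t.detach() - p).abs().mean()
    return total


def gram_matrix(features: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, C) channel co-activation matrix, normalized by
    C*H*W so the scale is resolution-independent."""
    n, c, h, w = features.shape
    f = features.reshape(n, c, h * w)
    return (f @ f.transpose(0, 2, 1)) * (1.0 / float(c * h * w))


def style_loss(extractor: Module, pred: Tensor, reference: Tensor,
               mask: np.ndarray | None = None) -> Tensor:
    """L1 distance between Gram matrices of deep features.

    When ``mask`` is given the prediction is first composited into the
    reference (reference outside the mask, prediction inside), matching how
    the restored image is assembled; the loss is then zero at perfect
    restoration.
    """
    if extractor is None:
        raise ValueError("feature extractor is not initialized")
    if pred.shape != reference.shape:
        raise ValueError("shape mismatch")
    if mask is not None:
        m = Tensor(mask.astype(np.float32))
        comp = reference.detach() * (1.0 - m) + pred * m
    else:
        comp = pred
    cf = extractor(comp)
    rf = extractor(reference.detach())
    total = Tensor(0.0)
    for c_feat, r_feat in zip(cf, rf):
        total = total + (gram_matrix(c_feat)
                         - gram_matrix(r_feat).detach()).abs().mean()
    return total


def edge_gan_objective(d_real: Tensor, d_fake: Tensor,
                       real_feats: list[Tensor], fake_feats: list[Tensor],
                       weights: LossWeights | None = None
                       ) -> tuple[Tensor, Tensor]:
    """(generator total, discriminator total) for the edge stage."""
    w = weights or LossWeights()
    g = (w.lambda_adv1 * adversarial_loss(None, d_fake, "generator")
         + w.lambda_fm * feature_matching_loss(real_feats, fake_feats))
    d = adversarial_loss(d_real, d_fake, "discriminator")
    return g, d


def content_gan_objective(pred: Tensor, target: Tensor,
                          d_real: Tensor, d_fake: Tensor,
                          extractor: Module,
                          mask: np.ndarray | None = None,
                          weights: LossWeights | None = None
                          ) -> tuple[Tensor, Tensor]:
    """(generator total, discriminator total) for the content stage."""
    w = weights or LossWeights()
    g = (w.lambda_l1 * l1_loss(pred, target.detach())
         + w.lambda_adv2 * adversarial_loss(None, d_fake, "generator")
         + w.lambda_perc * perceptual_loss(extractor, pred, target)
         + w.lambda_style * style_loss(extractor, pred, target, mask))
    d = adversarial_loss(d_real, d_fake, "discriminator")
    return g, d


class LossLogger:
    """Append per-step scalar losses to a JSONL file."""

    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path else None
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self._fh = open(self.path, "a")
        else:
            self._fh = None

    def log(self, step: int, **scalars: float) -> None:
        if self._fh:
            self._fh.write(json.dumps({"step": step, **scalars}) + "\n")
            self._fh.flush()

    def close(self):
        if self._fh:
            self._fh.close()
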