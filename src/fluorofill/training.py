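"""Two-stage progressive training and inference-time restoration.

Stage 1 (edge network) trains first on low-resolution images, then —
because every network is fully convolutional — continues with the same
weights on high-resolution images (progressive transfer).  Stage 2
(content network) trains against the frozen edge network's composited edge
maps.  Both stages alternate one discriminator step and one generator step
per iteration with Adam(lr=1e-4, beta1=0, beta2=0.9).

Within a batch all samples share one restoration mask (masks are sampled
per step from a pre-generated pool); images differ per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.morphology import closing, footprint_rectangle, remove_small_objects
from skimage.transform import resize

from .autograd import Adam, Tensor, concat, no_grad
from .losses import (LossLogger, LossWeights, content_gan_objective,
                     edge_gan_objective, TinyFeatureExtractor)
from .masks import canny_edges, composite_edge_map, random_mask
from .networks import (DiscriminatorConfig, EdgeGenerator, GeneratorConfig,
                       PatchDiscriminator, load_checkpoint, save_checkpoint)
from .screening import GrayImage

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Schedule, optimizer and model-size settings for one training run.

    The ``desk`` preset is the package default: small widths and step
    counts sized for a single CPU.  The ``fidelity`` preset carries the
    full-size reference schedule (1,000,000 edge + 200,000 content
    iterations at width 64); it is a configuration, not something the desk
    profile ever runs.
    """

    low_resolution: int = 64
    high_resolution: int = 128
    #: resolution of content-stage training and restoration; defaults to the
    #: dataset's native resolution (the low one) — only the edge stage is
    #: trained progressively
    content_resolution: int | None = None
    edge_iters_low: int = 1000
    edge_iters_high: int = 1000
    content_iters: int = 2000
    batch_size: int = 4
    base_width: int = 4
    lr: float = 1e-4
    beta1: float = 0.0
    beta2: float = 0.9
    mask_fraction: float = 0.2
    mask_pool_size: int = 32
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    log_path: str | None = None
    log_every: int = 50

    def __post_init__(self):
        if self.low_resolution >= self.high_resolution:
            raise ValueError("low_resolution must be < high_resolution")
        if self.content_resolution is None:
            self.content_resolution = self.low_resolution
        for name in ("edge_iters_low", "edge_iters_high", "content_iters",
                     "batch_size", "base_width"):
            if getattr(self, name) < 0 or (name in ("batch_size", "base_width")
                                           and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk(cls, **kw) -> "TrainingConfig":
        return cls(**kw)

    @classmethod
    def fidelity(cls, **kw) -> "TrainingConfig":
        defaults = dict(low_resolution=128, high_resolution=256,
                        content_resolution=256,
                        edge_iters_low=500_000, edge_iters_high=500_000,
                        content_iters=200_000, batch_size=8, base_width=64)
        defaults.update(kw)
        return cls(**defaults)


class _ResolutionDataset:
    """Clean images at one resolution with precomputed Canny edges and a
    pool of random restoration masks."""

    def __init__(self, images: Sequence[GrayImage], resolution: int,
                 mask_fraction: float, pool_size: int, seed: int):
        self.images = []
        self.edges = []
        for im in images:
            data = im.data
            if data.shape != (resolution, resolution):
                data = resize(data, (resolution, resolution),
                              anti_aliasing=True).astype(np.float32)
                data = np.clip(data, 0.0, 1.0)
            g = GrayImage(data, bit_depth=im.bit_depth)
            self.images.append(g)
            self.edges.append(canny_edges(g).astype(np.float32))
        self.masks = [random_mask((resolution, resolution), mask_fraction,
                                  style="blobs", seed=seed + 7000 + i)
                      for i in range(pool_size)]
        self.resolution = resolution

    def batch(self, rng: np.random.Generator, batch_size: int):
        """(gray, edges, mask) arrays; one shared mask per batch."""
        idx = rng.integers(0, len(self.images), size=batch_size)
        gray = np.stack([self.images[i].data for i in idx])[:, None]
        edges = np.stack([self.edges[i] for i in idx])[:, None]
        mask = self.masks[int(rng.integers(0, len(self.masks)))]
        return gray.astype(np.float32), edges.astype(np.float32), mask


def _edge_inputs(gray: np.ndarray, edges: np.ndarray, mask: np.ndarray):
    """Stack (masked gray filled with white, mask plane, masked edges)."""
    m = mask.astype(np.float32)[None, None]
    masked_gray = gray * (1.0 - m) + 1.0 * m
    masked_edges = edges * (1.0 - m)
    mask_plane = np.broadcast_to(m, gray.shape)
    return np.concatenate([masked_gray, mask_plane, masked_edges], axis=1)


def _edge_training_phase(g1, d1, opt_g, opt_d, data: _ResolutionDataset,
                         cfg: TrainingConfig, steps: int, rng,
                         log: LossLogger, step_offset: int) -> list[float]:
    trace = []
    for it in range(steps):
        gray, edges, mask = data.batch(rng, cfg.batch_size)
        x = Tensor(_edge_inputs(gray, edges, mask))
        gray_t, edges_t = Tensor(gray), Tensor(edges)

        fake = g1(x, mask)

        # discriminator step (features kept for the FM term, which
        # detaches them — no generator gradient flows through)
        opt_d.zero_grad()
        d_real, real_feats = d1(concat([edges_t, gray_t], axis=1),
                                return_features=True)
        d_fake = d1(concat([fake.detach(), gray_t], axis=1))
        _, d_loss = edge_gan_objective(d_real, d_fake, [], [], cfg.weights)
        d_loss.backward()
        opt_d.step()

        # generator step (against the updated discriminator)
        opt_g.zero_grad()
        d_fake2, fake_feats = d1(concat([fake, gray_t], axis=1),
                                 return_features=True)
        g_loss, _ = edge_gan_objective(d_real.detach(), d_fake2,
                                       real_feats, fake_feats, cfg.weights)
        g_loss.backward()
        opt_g.step()

        trace.append(g_loss.item())
        if it % cfg.log_every == 0:
            log.log(step_offset + it, g1_loss=g_loss.item(),
                    d1_loss=d_loss.item(), resolution=data.resolution)
    return trace


def train_edge_gan(images: Sequence[GrayImage], cfg: TrainingConfig,
                   checkpoint_path: str | Path | None = None
                   ) -> tuple[EdgeGenerator, PatchDiscriminator, dict]:
    """Progressive low-to-high-resolution training of the edge network.

    Phase A runs at ``low_resolution``; phase B rebuilds the data pipeline
    at ``high_resolution`` and continues with the same (fully
    convolutional) weights.  Returns the trained G1/D1 and the loss traces.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    g1 = EdgeGenerator(GeneratorConfig.edge(base_width=cfg.base_width,
                                            seed=cfg.seed))
    d1 = PatchDiscriminator(DiscriminatorConfig(in_channels=2,
                                                base_width=cfg.base_width,
                                                seed=cfg.seed + 1))
    opt_g = Adam(g1.parameters(), cfg.lr, cfg.beta1, cfg.beta2)
    opt_d = Adam(d1.parameters(), cfg.lr, cfg.beta1, cfg.beta2)
    log = LossLogger(cfg.log_path)

    traces = {}
    if cfg.edge_iters_low > 0:
        low = _ResolutionDataset(images, cfg.low_resolution,
                                 cfg.mask_fraction, cfg.mask_pool_size,
                                 cfg.seed)
        traces["low"] = _edge_training_phase(
            g1, d1, opt_g, opt_d, low, cfg, cfg.edge_iters_low, rng, log, 0)
    if cfg.edge_iters_high > 0:
        high = _ResolutionDataset(images, cfg.high_resolution,
                                  cfg.mask_fraction, cfg.mask_pool_size,
                                  cfg.seed + 1)
        traces["high"] = _edge_training_phase(
            g1, d1, opt_g, opt_d, high, cfg, cfg.edge_iters_high, rng, log,
            cfg.edge_iters_low)
    log.close()
    if checkpoint_path:
        save_checkpoint(checkpoint_path, {"g1": g1, "d1": d1},
                        {"g1": g1.cfg, "d1": d1.cfg},
                        cfg.edge_iters_low + cfg.edge_iters_high)
    return g1, d1, traces


def train_content_gan(images: Sequence[GrayImage],
                      edge_net: EdgeGenerator | str | Path,
                      cfg: TrainingConfig,
                      extractor: TinyFeatureExtractor | None = None,
                      checkpoint_path: str | Path | None = None
                      ) -> tuple[EdgeGenerator, PatchDiscriminator, dict]:
    """Train the content network against the frozen edge network."""
    if len(images) == 0:
        raise ValueError("empty training set")
    g1 = _resolve_edge_net(edge_net)
    g1.eval()
    rng = np.random.default_rng(cfg.seed + 100)
    g2 = EdgeGenerator(GeneratorConfig.content(base_width=cfg.base_width,
                                               seed=cfg.seed + 2))
    d2 = PatchDiscriminator(DiscriminatorConfig(in_channels=2,
                                                base_width=cfg.base_width,
                                                seed=cfg.seed + 3))
    opt_g = Adam(g2.parameters(), cfg.lr, cfg.beta1, cfg.beta2)
    opt_d = Adam(d2.parameters(), cfg.lr, cfg.beta1, cfg.beta2)
    extractor = extractor or TinyFeatureExtractor()
    log = LossLogger(cfg.log_path)
    data = _ResolutionDataset(images, cfg.content_resolution,
                              cfg.mask_fraction, cfg.mask_pool_size,
                              cfg.seed + 2)
    trace = []
    for it in range(cfg.content_iters):
        gray, edges, mask = data.batch(rng, cfg.batch_size)
        with no_grad():
            pred_edge = g1(Tensor(_edge_inputs(gray, edges, mask)), mask)
        m = mask.astype(np.float32)[None, None]
        comp = edges * (1.0 - m) + pred_edge.data * m
        masked_gray = gray * (1.0 - m) + 1.0 * m
        x = Tensor(np.concatenate([masked_gray, comp], axis=1))
        gray_t, comp_t = Tensor(gray), Tensor(comp)

        pred = g2(x, mask)

        opt_d.zero_grad()
        d_real = d2(concat([gray_t, comp_t], axis=1))
        d_fake = d2(concat([pred.detach(), comp_t], axis=1))
        _, d_loss = content_gan_objective(pred.detach(), gray_t, d_real,
                                          d_fake, extractor, mask,
                                          cfg.weights)
        d_loss.backward()
        opt_d.step()

        opt_g.zero_grad()
        d_fake2 = d2(concat([pred, comp_t], axis=1))
        g_loss, _ = content_gan_objective(pred, gray_t, d_real.detach(),
                                          d_fake2, extractor, mask,
                                          cfg.weights)
        g_loss.backward()
        opt_g.step()

        trace.append(g_loss.item())
        if it % cfg.log_every == 0:
            log.log(it, g2_loss=g_loss.item(), d2_loss=d_loss.item())
    log.close()
    if checkpoint_path:
        save_checkpoint(checkpoint_path, {"g2": g2, "d2": d2},
                        {"g2": g2.cfg, "d2": d2.cfg}, cfg.content_iters)
    return g2, d2, {"content": trace}


def _resolve_edge_net(edge_net) -> EdgeGenerator:
    if isinstance(edge_net, EdgeGenerator):
        return edge_net
    states, configs, _ = load_checkpoint(edge_net)
    g1 = EdgeGenerator(GeneratorConfig(**configs["g1"]))
    g1.load_state_dict(states["g1"])
    return g1


@dataclass
class RestorationResult:
    restored: GrayImage
    predicted_edge: np.ndarray
    mask: np.ndarray
    provenance: dict


def restore(image: GrayImage, mask: np.ndarray,
            g1: EdgeGenerator, g2: EdgeGenerator,
            provenance: dict | None = None) -> RestorationResult:
    """Full two-stage restoration of one image.

    The output is composited as ``image*(1-M) + G2(..)*M``: pixels outside
    the mask are bit-identical to the input.
    """
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if mask.max() == 0:
        return RestorationResult(GrayImage(image.data.copy(),
                                           image.bit_depth),
                                 np.zeros(image.shape, np.float32),
                                 mask, provenance or {})
    if mask.min() >= 1:
        logger.warning("mask covers the whole image: no context to borrow; "
                       "returning best-effort output")
    g1.eval()
    g2.eval()
    gray = image.data[None, None].astype(np.float32)
    edges = canny_edges(image).astype(np.float32)[None, None]
    with no_grad():
        pred_edge = g1(Tensor(_edge_inputs(gray, edges, mask)), mask)
        comp = composite_edge_map(edges[0, 0], pred_edge.data[0, 0], mask)
        m = mask.astype(np.float32)
        masked_gray = gray * (1.0 - m) + 1.0 * m
        x = np.concatenate([masked_gray, comp[None, None]], axis=1)
        out = g2(Tensor(x), mask).data[0, 0]
    restored = image.data * (1.0 - m) + out * m
    # the unmasked region must be bit-identical to the input
    restored[m == 0] = image.data[m == 0]
    return RestorationResult(GrayImage(np.clip(restored, 0, 1),
                                       image.bit_depth),
                             pred_edge.data[0, 0], mask, provenance or {})


def detect_artifact_mask(image: GrayImage, min_component: int = 16,
                         closing_size: int = 3) -> np.ndarray:
    """Saturated-pixel mask for unannotated artifact images.

    Pixels at the saturation value are morphologically closed (bridging
    one-pixel gaps inside a cluster) and components below
    ``min_component`` pixels are discarded — isolated saturated pixels are
    normal sensor behaviour, clusters are artifacts.
    """
    sat = image.data >= 1.0
    if not sat.any():
        return np.zeros(image.shape, dtype=np.uint8)
    closed = closing(
        sat, footprint_rectangle((closing_size, closing_size)))
    filtered = remove_small_objects(closed, max_size=min_component - 1)
    return filtered.astype(np.uint8)


def progressive_ablation(images: Sequence[GrayImage], cfg: TrainingConfig
                         ) -> dict[str, list[float]]:
    """Compare progressive (low->high) vs direct high-resolution training.

    Both arms get the same total number of edge iterations; returns the
    generator loss traces of each arm (no winner is asserted — at desk
    scale the comparison is stochastic).
    """
    total = cfg.edge_iters_low + cfg.edge_iters_high
    _, _, prog = train_edge_gan(images, cfg)
    from dataclasses import replace
    direct_cfg = replace(cfg, edge_iters_low=0, edge_iters_high=total)
    _, _, direct = train_edge_gan(images, direct_cfg)
    return {"progressive": prog.get("low", []) + prog.get("high", []),
            "direct": direct.get("high", [])}
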