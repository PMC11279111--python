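"""Generator and discriminator architectures of the two-stage model.

The edge generator G1 is an encoder / residual / decoder network with a
parallel contextual-attention branch; the two branch outputs are fused by
channel concatenation before the residual stack.  The discriminators are
70x70 PatchGANs with spectral normalization, emitting a sigmoid score map
(32 x 32 for a 256^2 input).  The content generator G2 repeats G1's layout
with all spectral normalization removed and half the residual depth.

``base_width`` scales every channel count together (64 = full-size
reference architecture; small values give desk-scale networks with the
identical layer structure).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .autograd import Conv2d, ConvTranspose2d, Module, Tensor, concat
from .attention import ContextualAttention


@dataclass
class GeneratorConfig:
    in_channels: int = 3            # gray + mask + masked edge for G1
    base_width: int = 64            # 64 reproduces the reference table
    n_resnet_blocks: int = 8        # 8 for G1, 4 for G2
    use_spectral_norm: bool = True  # True for G1, False for G2
    attention_branch: bool = True
    patch_size: int = 3
    softmax_scale: float = 10.0
    seed: int = 0
    paper_fidelity: bool = False    # strict reference-architecture checks

    def validate(self) -> None:
        if self.paper_fidelity:
            if self.n_resnet_blocks not in (4, 8):
                raise ValueError("reference architecture uses 4 or 8 "
                                 "residual blocks")
            if self.base_width != 64:
                raise ValueError("reference architecture uses base width 64")

    @classmethod
    def edge(cls, base_width: int = 64, **kw) -> "GeneratorConfig":
        return cls(in_channels=3, base_width=base_width, n_resnet_blocks=8,
                   use_spectral_norm=True, **kw)

    @classmethod
    def content(cls, base_width: int = 64, **kw) -> "GeneratorConfig":
        return cls(in_channels=2, base_width=base_width, n_resnet_blocks=4,
                   use_spectral_norm=False, **kw)


@dataclass
class DiscriminatorConfig:
    in_channels: int = 2            # score map is conditioned (map + image)
    base_width: int = 64
    seed: int = 0


class ResnetBlock(Module):
    """Two 3x3 convolutions (reflect-padded) with an additive skip."""

    def __init__(self, channels: int, spectral: bool,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, reflect_pad=1,
                            spectral=spectral, instance=True, act="relu",
                            rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, reflect_pad=1,
                            spectral=spectral, instance=True, act=None,
                            rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x))

    def summary_rows(self):
        return [self.conv1.summary_row(), self.conv2.summary_row()]


class EdgeGenerator(Module):
    """G1-style generator; also instantiates G2 via its config."""

    def __init__(self, cfg: GeneratorConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        bw = cfg.base_width
        sn = cfg.use_spectral_norm

        self.enc1 = Conv2d(cfg.in_channels, bw, 7, stride=1, reflect_pad=3,
                           spectral=sn, instance=True, act="relu", rng=rng)
        self.enc2 = Conv2d(bw, 2 * bw, 4, stride=2, pad=1,
                           spectral=sn, instance=True, act="relu", rng=rng)
        self.enc3 = Conv2d(2 * bw, 4 * bw, 4, stride=2, pad=1,
                           spectral=sn, instance=True, act="relu", rng=rng)
        encoder_out = 4 * bw

        if cfg.attention_branch:
            hb = max(bw // 2, 1)
            self.att1 = Conv2d(cfg.in_channels, hb, 5, stride=1, pad=2,
                               act="elu", rng=rng)
            self.att2 = Conv2d(hb, hb, 3, stride=2, pad=1, act="elu", rng=rng)
            self.att3 = Conv2d(hb, bw, 3, stride=1, pad=1, act="elu", rng=rng)
            self.att4 = Conv2d(bw, 2 * bw, 3, stride=2, pad=1, act="elu",
                               rng=rng)
            self.att5 = Conv2d(2 * bw, 2 * bw, 3, stride=1, pad=1, act="elu",
                               rng=rng)
            self.att6 = Conv2d(2 * bw, 2 * bw, 3, stride=1, pad=1, act="relu",
                               rng=rng)
            self.attention = ContextualAttention(cfg.patch_size,
                                                 cfg.softmax_scale)
            self.att7 = Conv2d(2 * bw, 2 * bw, 3, stride=1, pad=1, act="elu",
                               rng=rng)
            self.att8 = Conv2d(2 * bw, 2 * bw, 3, stride=1, pad=1, act="elu",
                               rng=rng)
            branch_out = 2 * bw
        else:
            branch_out = 0

        res_ch = encoder_out + branch_out
        self.res_channels = res_ch
        self.blocks = [ResnetBlock(res_ch, sn, rng)
                       for _ in range(cfg.n_resnet_blocks)]
        for i, blk in enumerate(self.blocks):
            self._modules[f"block{i}"] = blk

        self.dec1 = ConvTranspose2d(res_ch, 2 * bw, 4, stride=2, pad=1,
                                    spectral=sn, instance=True, act="relu",
                                    rng=rng)
        self.dec2 = ConvTranspose2d(2 * bw, bw, 4, stride=2, pad=1,
                                    spectral=sn, instance=True, act="relu",
                                    rng=rng)
        self.dec3 = Conv2d(bw, 1, 7, stride=1, reflect_pad=3, act="sigmoid",
                           rng=rng)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """``mask`` is the full-resolution binary mask (H, W); required when
        the attention branch is enabled."""
        x1 = self.enc3(self.enc2(self.enc1(x)))
        if self.cfg.attention_branch:
            if mask is None:
                raise ValueError("attention branch needs the mask")
            a = self.att6(self.att5(self.att4(self.att3(self.att2(
                self.att1(x))))))
            mask_ds = np.ascontiguousarray(mask[::4, ::4])
            a = self.attention(a, mask_ds)
            a = self.att8(self.att7(a))
            h = concat([x1, a], axis=1)
        else:
            h = x1
        for blk in self.blocks:
            h = blk(h)
        return self.dec3(self.dec2(self.dec1(h)))

    def summary(self) -> list[dict]:
        rows = [self.enc1.summary_row(), self.enc2.summary_row(),
                self.enc3.summary_row()]
        if self.cfg.attention_branch:
            rows += [self.att1.summary_row(), self.att2.summary_row(),
                     self.att3.summary_row(), self.att4.summary_row(),
                     self.att5.summary_row(), self.att6.summary_row(),
                     {"op": "ContextualAttention", "kernel": self.cfg.patch_size,
                      "channels": 2 * self.cfg.base_width, "stride": 1,
                      "norm": "", "act": ""},
                     self.att7.summary_row(), self.att8.summary_row()]
        rows += self.blocks[0].summary_rows()
        rows += [{"op": "ResNetBlocks", "kernel": 3,
                  "channels": self.res_channels, "stride": 1, "norm": "",
                  "act": "", "count": len(self.blocks)}]
        rows += [self.dec1.summary_row(), self.dec2.summary_row(),
                 self.dec3.summary_row()]
        return rows

    def spectral_layer_count(self) -> int:
        return sum(1 for m in self.modules()
                   if getattr(m, "spectral", False))


class PatchDiscriminator(Module):
    """70x70 PatchGAN with spectral norm and a sigmoid score map.

    The stride-1 4x4 layers use asymmetric (1, 2) padding so spatial size is
    preserved and a 256^2 input maps to exactly 32 x 32 scores.
    """

    def __init__(self, cfg: DiscriminatorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        bw = cfg.base_width
        self.conv1 = Conv2d(cfg.in_channels, bw, 4, stride=2, pad=1,
                            spectral=True, act="lrelu", rng=rng)
        self.conv2 = Conv2d(bw, 2 * bw, 4, stride=2, pad=1,
                            spectral=True, act="lrelu", rng=rng)
        self.conv3 = Conv2d(2 * bw, 4 * bw, 4, stride=2, pad=1,
                            spectral=True, act="lrelu", rng=rng)
        self.conv4 = Conv2d(4 * bw, 8 * bw, 4, stride=1, pad=(1, 2, 1, 2),
                            spectral=True, act="lrelu", rng=rng)
        self.conv5 = Conv2d(8 * bw, 1, 4, stride=1, pad=(1, 2, 1, 2),
                            act=None, rng=rng)

    def forward(self, x: Tensor, return_features: bool = False):
        f1 = self.conv1(x)
        f2 = self.conv2(f1)
        f3 = self.conv3(f2)
        f4 = self.conv4(f3)
        raw = self.conv5(f4)
        score = raw.leaky_relu(0.2).sigmoid()
        if return_features:
            return score, [f1, f2, f3, f4, score]
        return score

    def summary(self) -> list[dict]:
        rows = [self.conv1.summary_row(), self.conv2.summary_row(),
                self.conv3.summary_row(), self.conv4.summary_row()]
        last = self.conv5.summary_row()
        last["act"] = "lrelu/sigmoid"
        rows.append(last)
        return rows

    @staticmethod
    def receptive_field() -> int:
        """Receptive field of one output unit via r <- r + (k-1)*jump."""
        r, jump = 1, 1
        for k, s in [(4, 2), (4, 2), (4, 2), (4, 1), (4, 1)]:
            r += (k - 1) * jump
            jump *= s
        return r


def build_edge_generator(cfg: GeneratorConfig | None = None) -> EdgeGenerator:
    return EdgeGenerator(cfg or GeneratorConfig.edge())


def build_edge_discriminator(cfg: DiscriminatorConfig | None = None
                             ) -> PatchDiscriminator:
    return PatchDiscriminator(cfg or DiscriminatorConfig())


def build_content_generator(cfg: GeneratorConfig | None = None
                            ) -> EdgeGenerator:
    return EdgeGenerator(cfg or GeneratorConfig.content())


def build_content_discriminator(cfg: DiscriminatorConfig | None = None
                                ) -> PatchDiscriminator:
    return PatchDiscriminator(cfg or DiscriminatorConfig())


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(path: str | Path, modules: dict[str, Module],
                    configs: dict[str, object], step: int) -> None:
    """Single-file archive: weights as arrays, configs as embedded YAML."""
    arrays = {}
    for name, mod in modules.items():
        for key, value in mod.state_dict().items():
            arrays[f"{name}/{key}"] = value
    meta = {"step": int(step),
            "configs": {k: asdict(v) for k, v in configs.items()}}
    arrays["__meta__"] = np.frombuffer(
        yaml.safe_dump(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[dict[str, dict], dict, int]:
    """Returns (per-module state dicts, configs dict, step)."""
    with np.load(path) as data:
        meta = yaml.safe_load(bytes(data["__meta__"]).decode())
        states: dict[str, dict] = {}
        for key in data.files:
            if key == "__meta__":
                continue
            mod, _, param = key.partition("/")
            states.setdefault(mod, {})[param] = data[key]
    return states, meta["configs"], meta["step"]
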