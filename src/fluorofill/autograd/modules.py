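"""Layer modules built on the autograd engine."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

_ACTIVATIONS = ("relu", "lrelu", "elu", "sigmoid", None)


class Module:
    """Parameter container with named state, torch-like but tiny."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        p = Tensor(value, requires_grad=True)
        self._params[name] = p
        object.__setattr__(self, name, p)
        return p

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        object.__setattr__(self, name, value)
        return value

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name.startswith("buf:"):
                bufs[name[4:]][...] = value
            else:
                params[name].data[...] = np.asarray(value, dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _apply_activation(x: Tensor, act: str | None) -> Tensor:
    if act is None:
        return x
    if act == "relu":
        return x.relu()
    if act == "lrelu":
        return x.leaky_relu(0.2)
    if act == "elu":
        return x.elu()
    if act == "sigmoid":
        return x.sigmoid()
    raise ValueError(f"unknown activation {act!r}")


class Conv2d(Module):
    """Convolution with optional spectral norm, instance norm and activation
    (applied in that order), plus optional reflection pre-padding for the
    size-preserving 7x7 / 3x3 layers."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad=0, *, spectral: bool = False, instance: bool = False,
                 act: str | None = None, reflect_pad: int = 0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        assert act in _ACTIVATIONS
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.register_parameter(
            "weight", rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel))
            .astype(np.float32))
        self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.pad = stride, pad
        self.spectral, self.instance, self.act = spectral, instance, act
        self.reflect_pad = reflect_pad
        if spectral:
            u = rng.normal(size=out_ch).astype(np.float32)
            self.register_buffer("u", u / np.linalg.norm(u))

    def forward(self, x: Tensor) -> Tensor:
        if self.reflect_pad:
            p = self.reflect_pad
            x = x.pad2d((p, p, p, p), mode="reflect")
        w = self.weight
        if self.spectral:
            w = F.spectral_normalize(w, self.u, update=self.training)
        y = F.conv2d(x, w, self.bias, stride=self.stride, pad=self.pad)
        if self.instance:
            y = F.instance_norm(y)
        return _apply_activation(y, self.act)

    def summary_row(self) -> dict:
        norms = "/".join(n for n, on in (("S", self.spectral),
                                         ("I", self.instance)) if on)
        return {"op": "Conv", "kernel": self.kernel, "channels": self.out_ch,
                "stride": self.stride, "norm": norms, "act": self.act or ""}


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 pad: int = 1, *, spectral: bool = False, instance: bool = False,
                 act: str | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.register_parameter(
            "weight", rng.normal(0.0, scale, (in_ch, out_ch, kernel, kernel))
            .astype(np.float32))
        self.register_parameter("bias", np.zeros(out_ch, dtype=np.float32))
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.pad = stride, pad
        self.spectral, self.instance, self.act = spectral, instance, act
        if spectral:
            u = rng.normal(size=in_ch).astype(np.float32)
            self.register_buffer("u", u / np.linalg.norm(u))

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        if self.spectral:
            w = F.spectral_normalize(w, self.u, update=self.training)
        y = F.conv_transpose2d(x, w, self.bias, stride=self.stride,
                               pad=self.pad)
        if self.instance:
            y = F.instance_norm(y)
        return _apply_activation(y, self.act)

    def summary_row(self) -> dict:
        norms = "/".join(n for n, on in (("S", self.spectral),
                                         ("I", self.instance)) if on)
        return {"op": "TransposeConv", "kernel": self.kernel,
                "channels": self.out_ch, "stride": self.stride,
                "norm": norms, "act": self.act or ""}


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)
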