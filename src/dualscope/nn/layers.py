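"""Neural-network building blocks on top of the autodiff tensor.

Modules hold :class:`Parameter` leaves and non-trainable buffers (batch-norm
running statistics).  ``state_dict``/``load_state_dict`` use dotted attribute
paths so checkpoints round-trip through ``np.savez``.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- tree walking --------------------------------------------------------
    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}.")
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                yield path, v

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, val in state.items():
            if key in params:
                if params[key].data.shape != val.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data[...] = val
            elif key in buffers:
                buffers[key][...] = val
            else:
                raise KeyError(f"unknown state entry {key}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
        zero_init: bool = False,
    ):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kernel * kernel
        shape = (out_ch, in_ch, kernel, kernel)
        self.weight = Parameter(
            np.zeros(shape, np.float32) if zero_init else he_normal(rng, shape, fan_in)
        )
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
        )


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias=True):
        super().__init__()
        self.weight = Parameter(he_normal(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics while training, running
    exponential-average statistics at inference."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones((1, ch, 1, 1), np.float32))
        self.beta = Parameter(np.zeros((1, ch, 1, 1), np.float32))
        self.running_mean = np.zeros((1, ch, 1, 1), np.float32)
        self.running_var = np.ones((1, ch, 1, 1), np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training:
            scale = self.gamma * (1.0 / np.sqrt(self.running_var + self.eps))
            return scale * x + (self.beta - scale * Tensor(self.running_mean))
        # fused training-mode node: closed-form backward through the batch
        # statistics instead of a composite graph
        axes = (0, 2, 3)
        n_red = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=axes, keepdims=True)
        var = ((x.data - mu) ** 2).mean(axis=axes, keepdims=True)
        m = self.momentum
        self.running_mean[...] = (1 - m) * self.running_mean + m * mu
        self.running_var[...] = (1 - m) * self.running_var + m * var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * invstd
        gamma, beta = self.gamma, self.beta
        out = Tensor(gamma.data * xhat + beta.data,
                     _parents=(x, gamma, beta))

        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes, keepdims=True))
            if x.requires_grad:
                dxhat = g * gamma.data
                s1 = dxhat.sum(axis=axes, keepdims=True)
                s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                x._accum(invstd / n_red * (n_red * dxhat - s1 - xhat * s2))

        out._backward = bw
        return out


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout2d(Module):
    """Channel-wise dropout; the mask RNG is supplied per forward pass by the
    training loop so runs stay reproducible."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0 or self.rng is None:
            return x
        n, c = x.shape[:2]
        keep = (self.rng.random((n, c, 1, 1)) >= self.p).astype(x.dtype)
        return x * (keep / (1.0 - self.p))
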