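"""Neural building blocks on top of the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = ["Module", "Linear", "MLP", "GRUCell", "Conv1d"]


class Module:
    """Parameter container. Subclasses register parameters as Tensor
    attributes (requires_grad=True) or sub-Modules; `parameters()` walks both.
    """

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            _flatten_state(name, value, out)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)[:5]}")
        for name, value in vars(self).items():
            _load_state(name, value, state)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _flatten_state(prefix, value, out):
    if isinstance(value, Tensor) and value.requires_grad:
        out[prefix] = value.data
    elif isinstance(value, Module):
        for k, v in value.state_dict().items():
            out[f"{prefix}.{k}"] = v
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _flatten_state(f"{prefix}.{i}", v, out)
    elif isinstance(value, dict):
        for k, v in value.items():
            _flatten_state(f"{prefix}.{k}", v, out)


def _load_state(prefix, value, state):
    if isinstance(value, Tensor) and value.requires_grad:
        value.data = np.asarray(state[prefix], dtype=np.float64).reshape(value.data.shape)
    elif isinstance(value, Module):
        sub = {k[len(prefix) + 1:]: v for k, v in state.items() if k.startswith(prefix + ".")}
        value.load_state_dict(sub)
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _load_state(f"{prefix}.{i}", v, state)
    elif isinstance(value, dict):
        for k, v in value.items():
            _load_state(f"{prefix}.{k}", v, state)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """Feed-forward stack with ReLU between layers (linear final layer)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class GRUCell(Module):
    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.w_ih = Linear(input_dim, 3 * hidden_dim, rng)
        self.w_hh = Linear(hidden_dim, 3 * hidden_dim, rng)
        self.hidden_dim = hidden_dim

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        d = self.hidden_dim
        gi, gh = self.w_ih(x), self.w_hh(h)
        gi_r, gi_z, gi_n = _split3(gi, d)
        gh_r, gh_z, gh_n = _split3(gh, d)
        r = (gi_r + gh_r).sigmoid()
        z = (gi_z + gh_z).sigmoid()
        n = (gi_n + r * gh_n).tanh()
        return (1.0 - z) * n + z * h


def _split3(t: Tensor, d: int):
    cols = t.shape[-1]
    assert cols == 3 * d
    tt = t.transpose() if t.ndim == 2 else t.reshape(-1)
    if t.ndim == 2:
        a = tt.slice_rows(0, d).transpose()
        b = tt.slice_rows(d, 2 * d).transpose()
        c = tt.slice_rows(2 * d, 3 * d).transpose()
    else:
        a = tt.slice_rows(0, d)
        b = tt.slice_rows(d, 2 * d)
        c = tt.slice_rows(2 * d, 3 * d)
    return a, b, c


class Conv1d(Module):
    """1-D convolution over (length, channels) input with zero 'same' padding
    and configurable dilation, realized as gather + matmul.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator):
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.weight = Tensor(
            _glorot(rng, kernel_size * in_ch, out_ch), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.in_ch = in_ch

    def __call__(self, x: Tensor) -> Tensor:
        length = x.shape[0]
        k, d = self.kernel_size, self.dilation
        half = (k // 2) * d
        # pad with explicit zero rows so boundary taps read zeros
        pad = Tensor(np.zeros((half, self.in_ch)))
        xp = concat([pad, x, pad], axis=0)
        taps = [xp.slice_rows(j * d, j * d + length) for j in range(k)]
        stacked = concat(taps, axis=1)  # (length, k*in_ch)
        return stacked @ self.weight + self.bias
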