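"""Neural building blocks: linear, embedding, batch norm, LSTM cell, Adam."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm_train, concat


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        """All stateful arrays (parameters + running stats), in stable order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for a, s in zip(self.state_arrays(), state, strict=True):
            a[...] = s

    def checksum(self) -> float:
        return float(sum(np.abs(a).sum() for a in self.state_arrays()))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.W[np.asarray(ids, dtype=int)]


class BatchNorm1d(Module):
    """Batch normalization over the leading axes of (..., features)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            flat = x.reshape(-1, x.shape[-1])
            out, mu, var = batchnorm_train(flat, self.gamma, self.beta, self.eps)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
            return out.reshape(*x.shape)
        xn = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class MLP(Module):
    """Equal-width ReLU hidden layers, optional batch norm, linear output."""

    def __init__(
        self,
        n_in: int,
        hidden: int,
        n_layers: int,
        n_out: int,
        rng: np.random.Generator,
        batchnorm: bool = False,
    ):
        super().__init__()
        self.layers: list[Module] = []
        self.norms: list[Module] = []
        d = n_in
        for _ in range(n_layers):
            self.layers.append(Linear(d, hidden, rng))
            self.norms.append(BatchNorm1d(hidden) if batchnorm else None)
            d = hidden
        self.out = Linear(d, n_out, rng)

    def parameters(self):
        out = []
        for lay in self.layers:
            out.extend(lay.parameters())
        for nm in self.norms:
            if nm is not None:
                out.extend(nm.parameters())
        out.extend(self.out.parameters())
        return out

    def modules(self):
        out = [self]
        for lay in self.layers:
            out.extend(lay.modules())
        for nm in self.norms:
            if nm is not None:
                out.extend(nm.modules())
        out.extend(self.out.modules())
        return out

    def __call__(self, x: Tensor) -> Tensor:
        for lay, nm in zip(self.layers, self.norms):
            x = lay(x)
            if nm is not None:
                x = nm(x)
            x = x.relu()
        return self.out(x)


class LSTMCell(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(hidden)
        self.Wx = Parameter(rng.normal(0.0, scale, size=(n_in, 4 * hidden)))
        self.Wh = Parameter(rng.normal(0.0, scale, size=(hidden, 4 * hidden)))
        self.b = Parameter(np.zeros(4 * hidden))
        self.hidden = hidden

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = x_t @ self.Wx + h @ self.Wh + self.b
        H = self.hidden
        i = z[:, 0:H].sigmoid()
        f = z[:, H : 2 * H].sigmoid()
        o = z[:, 2 * H : 3 * H].sigmoid()
        g = z[:, 3 * H : 4 * H].tanh()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


def lstm_scan(
    cell: LSTMCell, x: Tensor, mask: np.ndarray, reverse: bool = False
) -> tuple[list[Tensor], Tensor]:
    """Run an LSTM over (B, L, F); padded steps (mask 0) hold state frozen.

    Returns per-timestep hidden states (in sequence order) and the final
    state, which for the reverse direction is the state after consuming
    the sequence back to its first character.
    """
    B, L, _ = x.shape
    h = Tensor(np.zeros((B, cell.hidden)))
    c = Tensor(np.zeros((B, cell.hidden)))
    order = range(L - 1, -1, -1) if reverse else range(L)
    outs: list[Tensor | None] = [None] * L
    for t in order:
        m = mask[:, t : t + 1]
        h_new, c_new = cell.step(x[:, t, :], h, c)
        h = h_new * m + h * (1.0 - m)
        c = c_new * m + c * (1.0 - m)
        outs[t] = h
    return outs, h  # type: ignore[return-value]


class Adam:
    """Adaptive-moment estimation optimizer."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
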