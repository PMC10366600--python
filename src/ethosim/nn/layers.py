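"""Neural layers on top of the autograd core: Linear, GRU, attention."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import expit

from .autograd import Tensor, concat, stack, get_default_dtype

__all__ = ["Module", "Linear", "GRULayer", "BiGRU", "LayerNorm",
           "MultiHeadSelfAttention", "glorot"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: Optional[tuple[int, ...]] = None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, shape or (fan_out, fan_in)),
                  requires_grad=True)


class Module:
    """Base class: parameter discovery, grad reset, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for x in v:
                    if isinstance(x, Module):
                        yield x
                        yield from x.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        def collect(obj):
            for v in obj.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    collect(v)
                elif isinstance(v, (list, tuple)):
                    for x in v:
                        if isinstance(x, Tensor) and x.requires_grad and id(x) not in seen:
                            seen.add(id(x))
                            params.append(x)
                        elif isinstance(x, Module):
                            collect(x)
        collect(self)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, d in zip(params, state):
            p.data = np.asarray(d, dtype=get_default_dtype()).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.W = glorot(rng, in_features, out_features)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)
        self.out_features = out_features

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            # flatten leading axes: one large GEMM beats stacked matmul
            lead = x.shape[:-1]
            y = x.reshape(-1, x.shape[-1]) @ self.W.transpose(1, 0) + self.b
            return y.reshape(*lead, self.out_features)
        return x @ self.W.transpose(1, 0) + self.b


class GRUCellParams(Module):
    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.Wx = glorot(rng, input_size, 3 * hidden, (3 * hidden, input_size))
        self.Wh = glorot(rng, hidden, 3 * hidden, (3 * hidden, hidden))
        self.bx = Tensor(np.zeros(3 * hidden), requires_grad=True)
        self.bh = Tensor(np.zeros(3 * hidden), requires_grad=True)
        self.hidden = hidden


def _gru_scan(xp: Tensor, Wh: Tensor, bh: Tensor, hidden: int,
              reverse: bool) -> Tensor:
    """Run a GRU over pre-projected inputs ``xp`` (B, T, 3H) -> (B, T, H).

    The whole time loop is one autograd node with a hand-derived
    backward (backpropagation through time), which avoids building a
    per-timestep graph.  Gate layout along the 3H axis: reset, update,
    candidate.
    """
    B, T, _ = xp.shape
    H = hidden
    order = range(T - 1, -1, -1) if reverse else range(T)
    Whd, bhd = Wh.data, bh.data
    h = np.zeros((B, H), dtype=xp.data.dtype)
    out = np.empty((B, T, H), dtype=xp.data.dtype)
    cache = []
    for t in order:
        gh = h @ Whd.T + bhd
        gx = xp.data[:, t, :]
        r = expit(gx[:, :H] + gh[:, :H])
        z = expit(gx[:, H:2 * H] + gh[:, H:2 * H])
        n = np.tanh(gx[:, 2 * H:] + r * gh[:, 2 * H:])
        h_prev = h
        h = (1.0 - z) * n + z * h_prev
        out[:, t, :] = h
        cache.append((t, r, z, n, gh[:, 2 * H:], h_prev))

    def backward(g):
        dxp = np.zeros_like(xp.data) if xp.requires_grad else None
        dWh = np.zeros_like(Whd) if Wh.requires_grad else None
        dbh = np.zeros_like(bhd) if bh.requires_grad else None
        dh = np.zeros((B, H), dtype=xp.data.dtype)
        for t, r, z, n, chn, h_prev in reversed(cache):
            dh = dh + g[:, t, :]
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dpre_n = dn * (1.0 - n ** 2)
            dr = dpre_n * chn
            dpre_r = dr * r * (1.0 - r)
            dpre_z = dz * z * (1.0 - z)
            dgh = np.concatenate([dpre_r, dpre_z, dpre_n * r], axis=1)
            dh_prev = dh_prev + dgh @ Whd
            if dWh is not None:
                dWh += dgh.T @ h_prev
            if dbh is not None:
                dbh += dgh.sum(axis=0)
            if dxp is not None:
                dxp[:, t, :] = np.concatenate([dpre_r, dpre_z, dpre_n], axis=1)
            dh = dh_prev
        if dxp is not None:
            xp._accumulate(dxp)
        if dWh is not None:
            Wh._accumulate(dWh)
        if dbh is not None:
            bh._accumulate(dbh)

    return Tensor._make(out, (xp, Wh, bh), backward)


class GRULayer(Module):
    """Single-direction gated recurrent layer over (batch, time, features)."""

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        super().__init__()
        self.cell = GRUCellParams(input_size, hidden, rng)
        self.reverse = reverse
        self.hidden = hidden

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (outputs (B, T, H), final hidden state (B, H))."""
        c = self.cell
        xp = x @ c.Wx.transpose(1, 0) + c.bx  # (B, T, 3H), one matmul
        out = _gru_scan(xp, c.Wh, c.bh, self.hidden, self.reverse)
        T = x.shape[1]
        h_last = out[:, 0, :] if self.reverse else out[:, T - 1, :]
        return out, h_last


class BiGRU(Module):
    """Bidirectional GRU; outputs concatenated along the feature axis."""

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = GRULayer(input_size, hidden, rng, reverse=False)
        self.bwd = GRULayer(input_size, hidden, rng, reverse=True)

    def __call__(self, x: Tensor) -> tuple[Tensor, tuple[Tensor, Tensor]]:
        of, hf = self.fwd(x)
        ob, hb = self.bwd(x)
        return concat([of, ob], axis=2), (hf, hb)


class LayerNorm(Module):
    """Normalization over the last axis, as a single fused autograd node."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        mu = x.data.mean(axis=-1, keepdims=True)
        xc = x.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        y = gamma.data * xhat + beta.data
        n = x.shape[-1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).reshape(-1, n).sum(axis=0))
            if beta.requires_grad:
                beta._accumulate(g.reshape(-1, n).sum(axis=0))
            if x.requires_grad:
                gx = g * gamma.data
                s1 = gx.sum(axis=-1, keepdims=True)
                s2 = (gx * xhat).sum(axis=-1, keepdims=True)
                x._accumulate(inv * (gx - s1 / n - xhat * s2 / n))

        return Tensor._make(y, (x, gamma, beta), backward)


class MultiHeadSelfAttention(Module):
    def __init__(self, width: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if width % n_heads:
            raise ValueError("width must be divisible by n_heads")
        self.n_heads = n_heads
        self.dk = width // n_heads
        self.qkv = Linear(width, 3 * width, rng)  # fused projection
        self.out = Linear(width, width, rng)
        self.width = width

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        W, H, dk = self.width, self.n_heads, self.dk
        qkv = self.qkv(x).reshape(B, T, 3, H, dk).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (B, H, T, dk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, W)
        return self.out(ctx)
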