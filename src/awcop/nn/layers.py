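"""Neural-network building blocks on top of :mod:`awcop.nn.autograd`.

Convolution is an im2col + GEMM pair with a hand-written backward; the LSTM
is a fused operation whose backward runs classic backprop-through-time in a
single closure (one graph node for 300 timesteps). Both choices keep the
autograd graph small enough that desk-scale training is practical on one CPU
core.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, softmax

__all__ = [
    "Module", "Linear", "Conv2d", "BatchNorm2d", "MaxPool2d",
    "ResidualBlock", "TokenSelfAttention", "LSTM",
    "global_avg_pool", "cross_entropy",
]


class Module:
    """Parameter container with recursive traversal and train/eval modes."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for k, v in self.__dict__.items():
            if k.startswith("_"):
                continue
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for k, v in m.__dict__.items():
                if not k.startswith("_") and isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_state(self) -> dict[str, np.ndarray]:
        """Flat state dict (parameters + buffers) for checkpointing."""
        state = {}
        for i, m in enumerate(self.modules()):
            tag = f"{i}:{type(m).__name__}"
            for k, v in m.__dict__.items():
                if k.startswith("_"):
                    continue
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{tag}.{k}"] = v.data
                elif isinstance(v, np.ndarray):
                    state[f"{tag}.{k}"] = v
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        if set(own) != set(state):
            raise ValueError("checkpoint state keys do not match model structure")
        for i, m in enumerate(self.modules()):
            tag = f"{i}:{type(m).__name__}"
            for k, v in m.__dict__.items():
                key = f"{tag}.{k}"
                if key in state:
                    if isinstance(v, Tensor):
                        v.data = np.array(state[key], dtype=np.float64)
                    else:
                        setattr(m, k, np.array(state[key]))

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """3x3 same-padding convolution (stride 1), im2col + GEMM."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.kernel = kernel
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                        (out_ch, fan_in)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        pad = k // 2
        w, b = self.weight, self.bias
        xd = x.data
        n, c, h, wdt = xd.shape
        xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        # windows: (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wdt, c * k * k)
        out = cols @ w.data.T + b.data
        out = out.reshape(n, h, wdt, -1).transpose(0, 3, 1, 2)

        def backward(g):
            gf = g.transpose(0, 2, 3, 1).reshape(n * h * wdt, -1)
            if w.requires_grad:
                w._accumulate(gf.T @ cols)
            if b.requires_grad:
                b._accumulate(gf.sum(axis=0))
            if x.requires_grad:
                dcols = (gf @ w.data).reshape(n, h, wdt, c, k, k)
                dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N, C, k, k, H, W)
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i:i + h, j:j + wdt] += dcols[:, :, i, j]
                x._accumulate(dxp[:, :, pad:pad + h, pad:pad + wdt])

        return Tensor._make(out, (x, w, b), backward)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        xd = x.data
        axes = (0, 2, 3)
        if self.training:
            mean = xd.mean(axis=axes)
            var = xd.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
                if training:
                    gm = g.mean(axis=axes)[None, :, None, None]
                    gxh = (g * xhat).mean(axis=axes)[None, :, None, None]
                    x._accumulate(gs * (g - gm - xhat * gxh))
                else:
                    x._accumulate(gs * g)

        return Tensor._make(out, (x, gamma, beta), backward)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2; requires even spatial dims."""

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d(2) requires even spatial dimensions")
        h2, w2 = h // 2, w // 2
        r = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h2, w2, 4)
        idx = r.argmax(axis=-1)  # first max wins ties
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if not x.requires_grad:
                return
            onehot = np.eye(4)[idx] * g[..., None]
            dx = onehot.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(dx.reshape(n, c, h, w))

        return Tensor._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Adaptive average pool to 1x1, returned as (N, C)."""
    return x.mean(axis=3).mean(axis=2)


class ResidualBlock(Module):
    """He-style basic block: two 3x3 convs at constant width, identity skip."""

    def __init__(self, n_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(n_ch, n_ch, rng)
        self.bn1 = BatchNorm2d(n_ch)
        self.conv2 = Conv2d(n_ch, n_ch, rng)
        self.bn2 = BatchNorm2d(n_ch)

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + x).relu()


class TokenSelfAttention(Module):
    """Single-head scaled dot-product self-attention over a token axis.

    Input (N, T, D_tok); output the same shape. Used both to re-weight a
    branch embedding reshaped into tokens and to mix the four modality
    embeddings in attention fusion.
    """

    def __init__(self, d_tok: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / d_tok)
        self.wq = Tensor(rng.normal(0, scale, (d_tok, d_tok)), requires_grad=True)
        self.wk = Tensor(rng.normal(0, scale, (d_tok, d_tok)), requires_grad=True)
        self.wv = Tensor(rng.normal(0, scale, (d_tok, d_tok)), requires_grad=True)
        self.d_tok = d_tok

    def __call__(self, x: Tensor) -> Tensor:
        q = x.matmul(self.wq)
        k = x.matmul(self.wk)
        v = x.matmul(self.wv)
        scores = q.matmul(k.transpose((0, 2, 1))) * (1.0 / np.sqrt(self.d_tok))
        attn = softmax(scores, axis=-1)
        return attn.matmul(v)


class LSTM(Module):
    """Single-layer LSTM; ``last_hidden`` collapses (N, T, I) -> (N, H).

    Forward caches gate activations; backward is fused truncated-free BPTT
    over the full sequence, emitting gradients for the three weight tensors
    and (when requested) the input — the latter drives waveform saliency.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        h = hidden_size
        s_i = np.sqrt(1.0 / max(input_size, 1))
        s_h = np.sqrt(1.0 / h)
        self.w_ih = Tensor(rng.normal(0, s_i, (input_size, 4 * h)), requires_grad=True)
        self.w_hh = Tensor(rng.normal(0, s_h, (h, 4 * h)), requires_grad=True)
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0  # forget-gate bias opens the memory path at init
        self.bias = Tensor(b, requires_grad=True)
        self.hidden_size = h

    def last_hidden(self, x: Tensor) -> Tensor:
        w_ih, w_hh, bias = self.w_ih, self.w_hh, self.bias
        xd = x.data
        n, t, _ = xd.shape
        hsz = self.hidden_size

        def sig(z):
            return 1.0 / (1.0 + np.exp(-z))

        xproj = xd.reshape(n * t, -1) @ w_ih.data
        xproj = xproj.reshape(n, t, 4 * hsz) + bias.data
        h = np.zeros((n, hsz))
        c = np.zeros((n, hsz))
        cache = []
        for step in range(t):
            a = xproj[:, step] + h @ w_hh.data
            i = sig(a[:, :hsz])
            f = sig(a[:, hsz:2 * hsz])
            g = np.tanh(a[:, 2 * hsz:3 * hsz])
            o = sig(a[:, 3 * hsz:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            cache.append((i, f, g, o, c_prev, h_prev, tc))
        h_last = h

        def backward(grad_h):
            dw_ih = np.zeros_like(w_ih.data)
            dw_hh = np.zeros_like(w_hh.data)
            db = np.zeros_like(bias.data)
            dx = np.zeros_like(xd) if x.requires_grad else None
            dh = grad_h.copy()
            dc = np.zeros_like(dh)
            for step in range(t - 1, -1, -1):
                i, f, g, o, c_prev, h_prev, tc = cache[step]
                do = dh * tc
                dc = dc + dh * o * (1 - tc * tc)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                da = np.concatenate([
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ], axis=1)
                dw_hh += h_prev.T @ da
                dw_ih += xd[:, step].T @ da
                db += da.sum(axis=0)
                dh = da @ w_hh.data.T
                dc = dc * f
                if dx is not None:
                    dx[:, step] = da @ w_ih.data.T
            if w_ih.requires_grad:
                w_ih._accumulate(dw_ih)
            if w_hh.requires_grad:
                w_hh._accumulate(dw_hh)
            if bias.requires_grad:
                bias._accumulate(db)
            if dx is not None:
                x._accumulate(dx)

        return Tensor._make(h_last, (x, w_ih, w_hh, bias), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None,
                  reduction: str = "mean") -> Tensor:
    """Softmax cross-entropy with optional per-class weights (fused op)."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[labels]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)) * w
    denom = w.sum() if reduction == "mean" else 1.0
    out = nll.sum() / denom

    def backward(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            grad *= (w / denom)[:, None]
            logits._accumulate(grad * g)

    return Tensor._make(np.asarray(out), (logits,), backward)
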