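"""Neural-network layers on the minimal autodiff engine.

Layout convention is ``(B, C, H, W)`` throughout.  Convolution is computed by
im2col (strided-view patch extraction followed by one matmul), which is the
standard way to make small convolutions fast in pure numpy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor

__all__ = [
    "Module", "Conv2d", "InstanceNorm2d", "MaxPool2d", "UpsampleBilinear2d",
    "Linear", "Sequential", "ReLU",
]


class Module:
    """Base class: tracks parameters and child modules by attribute."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._collect_state(out, "")
        return out

    def _collect_state(self, out: dict, prefix: str) -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v.data.copy()
            elif isinstance(v, Module):
                v._collect_state(out, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(out, f"{key}.{i}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._collect_refs(own, "")
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for key, tensor in own.items():
            tensor.data = np.asarray(state[key], dtype=tensor.data.dtype
                                     ).reshape(tensor.data.shape)

    def _collect_refs(self, out: dict, prefix: str) -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v
            elif isinstance(v, Module):
                v._collect_refs(out, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_refs(out, f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B,C,H,W) -> (B, Hout, Wout, C, kh, kw) as a strided view."""
    B, C, H, W = x.shape
    Hout = (H - kh) // stride + 1
    Wout = (W - kw) // stride + 1
    sb, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(B, Hout, Wout, C, kh, kw),
        strides=(sb, sh * stride, sw * stride, sc, sh, sw),
        writeable=False,
    )


class Conv2d(Module):
    """2-D convolution (cross-correlation) with 'same'-style zero padding.

    He-normal weight initialization; bias zero.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding = (kernel // 2) if padding is None else padding
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.padding
        w, b = self.weight, self.bias
        xd = x.data
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        B, C, Hp, Wp = xd.shape
        Hout = (Hp - k) // s + 1
        Wout = (Wp - k) // s + 1
        cols = _im2col(xd, k, k, s).reshape(B * Hout * Wout, C * k * k)
        wmat = w.data.reshape(self.out_ch, C * k * k)
        out = (cols @ wmat.T + b.data).reshape(B, Hout, Wout, self.out_ch)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(B * Hout * Wout, self.out_ch)
            if b._tracks():
                b._accumulate(gmat.sum(axis=0))
            if w._tracks():
                w._accumulate((gmat.T @ cols).reshape(w.data.shape))
            if x._tracks():
                if s == 1:
                    # dx = full correlation of g with the flipped, in/out-
                    # transposed kernel — one im2col matmul instead of a
                    # patch scatter
                    gp = np.pad(np.ascontiguousarray(g),
                                ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
                    gcols = _im2col(gp, k, k, 1).reshape(-1, self.out_ch * k * k)
                    wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                    dx = (gcols @ wflip.reshape(C, -1).T).reshape(B, Hp, Wp, C)
                    dx = dx.transpose(0, 3, 1, 2)
                else:
                    dcols = (gmat @ wmat).reshape(B, Hout, Wout, C, k, k)
                    dx = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
                    for i in range(k):
                        for j in range(k):
                            dx[:, :, i:i + Hout * s:s, j:j + Wout * s:s] += \
                                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if p:
                    dx = dx[:, :, p:-p or None, p:-p or None]
                x._accumulate(dx)

        return Tensor._from_op(out, (x, w, b), backward)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with learnable affine scale/shift."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, ch, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class MaxPool2d(Module):
    """2x2 max pooling, stride 2."""

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        view = x.data[:, :, :Ho * 2, :Wo * 2].reshape(B, C, Ho, 2, Wo, 2)
        patches = view.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, 4)
        arg = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            dpatches = np.zeros_like(patches)
            np.put_along_axis(dpatches, arg[..., None], g[..., None], axis=-1)
            dx = dpatches.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            full = np.zeros_like(x.data)
            full[:, :, :Ho * 2, :Wo * 2] = dx.reshape(B, C, Ho * 2, Wo * 2)
            x._accumulate(full)

        return Tensor._from_op(out, (x,), backward)


def _linear_interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    M = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        M[i, lo_c] += 1.0 - frac
        M[i, hi_c] += frac
    return M


class UpsampleBilinear2d(Module):
    """Bilinear 2x upsampling, expressed as two fixed 1-D linear maps."""

    def __init__(self):
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def _mat(self, n_in: int) -> np.ndarray:
        key = (2 * n_in, n_in)
        if key not in self._cache:
            self._cache[key] = _linear_interp_matrix(2 * n_in, n_in)
        return self._cache[key]

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        Uh, Uw = self._mat(H), self._mat(W)
        out = np.einsum("ph,bchw,qw->bcpq", Uh, x.data, Uw, optimize=True)

        def backward(g):
            x._accumulate(np.einsum("ph,bcpq,qw->bchw", Uh, g, Uw, optimize=True))

        return Tensor._from_op(out, (x,), backward)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / n_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.mods = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
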