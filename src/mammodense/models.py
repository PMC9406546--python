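"""Segmentation architectures.

Four related models share one trunk:

* **U-Net** — encoder/decoder with skip connections; outputs a per-pixel
  2-class probability map (background, dense).
* **ECNN** — the encoder alone feeding a parameter branch; outputs the two
  threshold-tool parameters ``(alpha_bright, th_f)`` as image-level features.
* **Y-Net** — U-Net plus the parameter branch mounted on the bottleneck:
  mask and parameters jointly.
* **CM heads** — optional per-annotator heads on the final decoder features
  that emit a per-pixel 2x2 column-stochastic confusion matrix
  ``A[i, j] = P(annotator says i | true class j)``, enabling training from
  multiple noisy expert annotations.

Everything is expressed on the package's numpy autodiff engine; forward
passes are deterministic given fixed weights and input.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ShapeMismatch
from .nn import (AdamW, Conv2d, InstanceNorm2d, MaxPool2d, Module, Linear,
                 Tensor, UpsampleBilinear2d, concat)
from .parametric import ALPHA_BOX, SegmentationParams, DenseMask

__all__ = [
    "NetworkConfig", "DenseTissueNet", "build_model", "apply_confusion",
    "predict", "save_checkpoint", "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``encoder_channels`` double per down-sampling stage (default 24/48/96);
    ``param_branch_channels`` are the three stride-2 convolutions that reduce
    the bottleneck to a vector before the 2-unit projection.  ``heads``
    selects the outputs: ``mask`` (U-Net decoder), ``params`` (Y-Net/ECNN
    branch), ``cm`` (one confusion head per annotator).
    """

    encoder_channels: tuple[int, int, int] = (24, 48, 96)
    param_branch_channels: tuple[int, int, int] = (96, 128, 128)
    input_size: int = 256
    n_annotators: int = 0
    heads: tuple[str, ...] = ("mask",)

    def __post_init__(self):
        self.encoder_channels = tuple(self.encoder_channels)
        self.param_branch_channels = tuple(self.param_branch_channels)
        self.heads = tuple(self.heads)
        n_down = len(self.encoder_channels)
        if self.input_size % (2 ** n_down):
            raise ShapeMismatch(
                f"input_size {self.input_size} not divisible by 2^{n_down}")
        for a, b in zip(self.encoder_channels, self.encoder_channels[1:]):
            if b != 2 * a:
                raise ValueError("encoder channels must double per stage")
        if "cm" in self.heads and self.n_annotators < 1:
            raise ValueError("cm head requires n_annotators >= 1")
        if "cm" in self.heads and "mask" not in self.heads:
            raise ValueError("cm head requires the mask decoder")
        if not self.heads:
            raise ValueError("at least one head required")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in d.items()})


class DoubleConv(Module):
    """conv3x3 -> instance norm -> ReLU, twice."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng=rng)
        self.norm1 = InstanceNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.norm2 = InstanceNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(x)).relu()


class ParamBranch(Module):
    """Bottleneck -> three stride-2 3x3 convolutions -> global average pool
    -> 2-unit projection, squashed into the parameter boxes:
    ``th_f = sigmoid(z)`` in [0,1]; ``alpha_bright = softplus(z')`` clipped
    to (0, 4].  The projection bias is initialized so the branch starts at
    the neutral point (alpha 1, th_f 0.5)."""

    def __init__(self, c_in: int, channels: tuple[int, int, int],
                 rng: np.random.Generator):
        chans = [c_in, *channels]
        self.convs = [Conv2d(chans[i], chans[i + 1], 3, stride=2, padding=1, rng=rng)
                      for i in range(3)]
        self.proj = Linear(chans[-1], 2, rng=rng)
        # zero weights + neutral bias: every draw starts exactly at
        # (alpha 1, th_f 0.5), so the branch walks from the identity
        # correction instead of a random offset that may saturate the boxes
        self.proj.weight.data[:] = 0.0
        self.proj.bias.data[:] = (np.log(np.expm1(1.0)), 0.0)

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).relu()
        x = x.mean(axis=(2, 3))          # global average pool -> (B, C)
        z = self.proj(x)
        alpha = z[:, 0:1].softplus().clip(1e-6, ALPHA_BOX[1])
        th_f = z[:, 1:2].sigmoid()
        return concat([alpha, th_f], axis=1)   # (B, 2)


class DenseTissueNet(Module):
    """The shared trunk with configurable heads.

    ``forward`` returns a dict with the outputs selected by ``cfg.heads``:
    ``probs`` (B, 2, H, W) softmax per pixel; ``params`` (B, 2) as
    (alpha_bright, th_f); ``cms`` (B, n, 2, 2, H, W) column-stochastic.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        c1, c2, c3 = cfg.encoder_channels
        self.enc1 = DoubleConv(1, c1, rng)
        self.enc2 = DoubleConv(c1, c2, rng)
        self.enc3 = DoubleConv(c2, c3, rng)
        self.pool = MaxPool2d()
        self.bottleneck = DoubleConv(c3, c3, rng)
        if "mask" in cfg.heads:
            self.up = UpsampleBilinear2d()
            self.dec3 = DoubleConv(c3 + c3, c3, rng)
            self.dec2 = DoubleConv(c3 + c2, c2, rng)
            self.dec1 = DoubleConv(c2 + c1, c1, rng)
            self.head_mask = Conv2d(c1, 2, kernel=1, rng=rng)
        if "params" in cfg.heads:
            self.param_branch = ParamBranch(c3, cfg.param_branch_channels, rng)
        if "cm" in cfg.heads:
            self.cm_heads = [Conv2d(c1, 4, kernel=1, rng=rng)
                             for _ in range(cfg.n_annotators)]
            for head in self.cm_heads:
                # Start diagonally dominant (~0.9 on the diagonal): the
                # estimated annotators begin mostly reliable, which anchors
                # the identifiable basin the trace warm-up then reinforces.
                # All heads share one initialization so that any common
                # regularization pressure moves them in lock-step and only
                # the per-annotator label signal differentiates them.
                head.weight.data[:] = self.cm_heads[0].weight.data
                head.bias.data[:] = (2.2, 0.0, 0.0, 2.2)

    def forward(self, x: Tensor) -> dict:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ShapeMismatch(f"expected (B, 1, H, W) input, got {x.shape}")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ShapeMismatch("spatial dims must be divisible by 8")
        s1 = self.enc1(x)
        s2 = self.enc2(self.pool(s1))
        s3 = self.enc3(self.pool(s2))
        bott = self.bottleneck(self.pool(s3))
        out: dict = {}
        if "mask" in self.cfg.heads:
            d3 = self.dec3(concat([self.up(bott), s3], axis=1))
            d2 = self.dec2(concat([self.up(d3), s2], axis=1))
            d1 = self.dec1(concat([self.up(d2), s1], axis=1))
            out["probs"] = self.head_mask(d1).softmax(axis=1)
            if "cm" in self.cfg.heads:
                B, _, H, W = x.shape
                cms = []
                for head in self.cm_heads:
                    raw = head(d1).reshape(B, 2, 2, H, W)
                    # softmax over rows i for each column j: column-stochastic
                    cms.append(raw.softmax(axis=1))
                out["cms"] = cms
        if "params" in self.cfg.heads:
            out["params"] = self.param_branch(bott)
        return out


def build_model(arch: str, input_size: int = 256, n_annotators: int = 0,
                encoder_channels: tuple[int, int, int] = (24, 48, 96),
                cm: bool = False, seed: int | None = None) -> DenseTissueNet:
    """Construct one of the named architectures: ``ecnn``, ``unet``, ``ynet``.

    ``cm=True`` adds the per-annotator confusion heads (requires the mask
    decoder, hence ``unet`` or ``ynet``)."""
    heads = {"ecnn": ("params",), "unet": ("mask",), "ynet": ("mask", "params")}
    if arch not in heads:
        raise ValueError(f"unknown architecture {arch!r}")
    h = heads[arch]
    if cm:
        if "mask" not in h:
            raise ValueError("confusion heads require a mask decoder (unet/ynet)")
        h = h + ("cm",)
    c3 = encoder_channels[2]
    branch = (c3, (c3 * 4) // 3, (c3 * 4) // 3) if c3 != 96 else (96, 128, 128)
    cfg = NetworkConfig(encoder_channels=encoder_channels,
                        param_branch_channels=branch,
                        input_size=input_size, n_annotators=n_annotators, heads=h)
    return DenseTissueNet(cfg, np.random.default_rng(seed))


def apply_confusion(y_theta: Tensor, cm: Tensor) -> Tensor:
    """Push the estimated true distribution through an annotator's confusion
    field: per pixel ``y_r[i] = sum_j A[i, j] * y[j]``.

    ``y_theta`` is (B, 2, H, W), ``cm`` is (B, 2, 2, H, W); column-stochastic
    fields map distributions to distributions."""
    if not isinstance(y_theta, Tensor):
        y_theta = Tensor(y_theta)
    if not isinstance(cm, Tensor):
        cm = Tensor(cm)
    B, C, H, W = y_theta.shape
    if cm.shape != (B, C, C, H, W):
        raise ShapeMismatch(f"confusion field {cm.shape} does not match "
                            f"probability map {y_theta.shape}")
    return (cm * y_theta.reshape(B, 1, C, H, W)).sum(axis=2)


def predict(x: np.ndarray, model: DenseTissueNet, breast_mask: np.ndarray,
            binarize_at: float = 0.5):
    """Inference: dense-channel probability thresholded at ``binarize_at``
    and intersected with the breast mask.

    Returns ``(DenseMask, SegmentationParams | None)``.  For a parameters-only
    model (ECNN) the mask is reconstructed from the predicted parameters.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, None]
    out = model(Tensor(x))
    params = None
    if "params" in out:
        a, t = out["params"].data[0]
        params = SegmentationParams(float(a), float(t))
    if "probs" in out:
        dense = out["probs"].data[0, 1] >= binarize_at
        mask = DenseMask(dense & np.asarray(breast_mask, bool), source="network")
    else:
        corrected = np.clip(params.alpha_bright * x[0, 0], 0.0, 1.0)
        mask = DenseMask((corrected >= params.th_f) & np.asarray(breast_mask, bool),
                         source="parametric")
    return mask, params


def save_checkpoint(path: str | Path, model: DenseTissueNet,
                    variation: str | None = None) -> None:
    """Single-file archive: weights (npz) + config JSON + training-variation tag."""
    meta = {"config": model.cfg.to_dict(), "variation": variation}
    np.savez_compressed(path, __meta__=np.frombuffer(
        zlib.compress(json.dumps(meta).encode()), dtype=np.uint8),
        **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[DenseTissueNet, str | None]:
    with np.load(path) as data:
        meta = json.loads(zlib.decompress(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = DenseTissueNet(NetworkConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model, meta.get("variation")
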