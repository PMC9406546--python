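"""The composite training objective.

The total loss couples three networks: the segmentation trunk (theta), the
annotation heads (phi), and the parameter branch (rho):

    L_total = L(theta) + alpha_loss * L(phi) + beta_loss * L(rho)

* ``L(theta)`` sums, over annotators, the Dice loss between each annotator's
  noisy mask and the trunk's prediction pushed through that annotator's
  estimated confusion field — the model explains each expert's labels as a
  corruption of one shared underlying segmentation.
* ``L(phi)`` is the summed trace of the estimated confusion matrices.
  Minimizing it drives the estimated annotators toward maximal unreliability,
  which is what disentangles annotator noise from the true label
  distribution (many (CM, segmentation) pairs fit the labels equally well;
  the minimal-trace pair is the identifiable one).
* ``L(rho)`` ties the parameter branch to the trunk: the Dice loss between
  the trunk's probability map and the soft mask reconstructed from the
  predicted threshold parameters.

Weights default to ``alpha_loss = 0.9`` and ``beta_loss = 0.1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnnotatorCountMismatch, MammodenseError, ShapeMismatch
from .models import apply_confusion
from .nn import Tensor
from .parametric import ALPHA_BOX, SOFT_STEEPNESS

__all__ = ["LossWeights", "dice_loss", "annotator_loss", "trace_term",
           "parametric_loss", "soft_reconstruct_t", "total_loss",
           "DICE_SMOOTHING"]

DICE_SMOOTHING = 1e-6


@dataclass
class LossWeights:
    """alpha_loss weights the trace term; beta_loss the parametric term."""

    alpha_loss: float = 0.9
    beta_loss: float = 0.1

    def __post_init__(self):
        if self.alpha_loss < 0 or self.beta_loss < 0:
            raise ValueError("loss weights must be non-negative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def dice_loss(pred, target, eps: float = DICE_SMOOTHING) -> Tensor:
    """Soft Dice loss: ``1 - (2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps)``.

    ``pred`` holds per-pixel probabilities in [0,1]; ``target`` a binary mask
    of the same shape.  Sums run over the whole array (batch pooled)."""
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ShapeMismatch(f"pred {pred.shape} vs target {target.shape}")
    inter = (pred * target).sum()
    return 1.0 - (2.0 * inter + eps) / (pred.sum() + float(target.sum()) + eps)


def annotator_loss(y_theta, cms, labels) -> Tensor:
    """``L(theta)``: sum over annotators r of
    ``dice_loss(dense channel of A_r . y_theta, y_r)`` (no 1/n)."""
    if len(cms) != len(labels):
        raise AnnotatorCountMismatch(f"{len(cms)} confusion fields vs "
                                     f"{len(labels)} label sets")
    y_theta = _as_tensor(y_theta)
    total = None
    for cm, lab in zip(cms, labels):
        y_r = apply_confusion(y_theta, _as_tensor(cm))
        term = dice_loss(y_r[:, 1], np.asarray(lab, dtype=np.float64))
        total = term if total is None else total + term
    return total


def trace_term(cms, reduction: str = "mean") -> Tensor:
    """``L(phi)``: sum over annotators of the spatial mean (or sum) of the
    per-pixel confusion-matrix traces.  The mean keeps the term O(1) in the
    image resolution so ``alpha_loss`` transfers across input sizes."""
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    total = None
    for cm in cms:
        cm = _as_tensor(cm)                      # (B, 2, 2, H, W)
        tr = cm[:, 0, 0] + cm[:, 1, 1]
        term = tr.mean() if reduction == "mean" else tr.sum()
        total = term if total is None else total + term
    return total


def soft_reconstruct_t(image: np.ndarray, params: Tensor, breast: np.ndarray,
                       steepness: float = SOFT_STEEPNESS) -> Tensor:
    """Differentiable parametric reconstruction on the autodiff graph.

    ``params`` is the (B, 2) branch output (alpha_bright, th_f); the result
    is ``sigmoid(k * (clip(alpha * I, 0, 1) - th_f))`` masked to the breast.
    This is the only path through which gradients reach the rho branch."""
    image = np.asarray(image, dtype=np.float64)     # (B, H, W)
    breast = np.asarray(breast, dtype=np.float64)
    B = image.shape[0]
    alpha = params[:, 0].reshape(B, 1, 1)
    th_f = params[:, 1].reshape(B, 1, 1)
    corrected = (alpha * Tensor(image)).clip(0.0, 1.0)
    return ((corrected - th_f) * steepness).sigmoid() * Tensor(breast)


def parametric_loss(y_theta, image, params, breast,
                    steepness: float = SOFT_STEEPNESS) -> Tensor:
    """``L(rho)``: Dice loss between the trunk's dense channel and the soft
    parametric reconstruction."""
    y_theta = _as_tensor(y_theta)
    recon = soft_reconstruct_t(image, params, breast, steepness)
    dense = y_theta[:, 1]
    inter = (recon * dense).sum()
    return 1.0 - (2.0 * inter + DICE_SMOOTHING) / (
        recon.sum() + dense.sum() + DICE_SMOOTHING)


def total_loss(l_theta=None, l_phi=None, l_rho=None,
               weights: LossWeights = LossWeights()) -> Tensor:
    """``L(theta) + alpha_loss * L(phi) + beta_loss * L(rho)``; terms the
    model lacks are simply omitted."""
    parts = []
    if l_theta is not None:
        parts.append(_as_tensor(l_theta))
    if l_phi is not None:
        parts.append(weights.alpha_loss * _as_tensor(l_phi))
    if l_rho is not None:
        parts.append(weights.beta_loss * _as_tensor(l_rho))
    if not parts:
        raise MammodenseError("no loss terms supplied")
    out = parts[0]
    for p in parts[1:]:
        out = out + p
    if not np.isfinite(out.data):
        raise MammodenseError(f"non-finite loss {out.data}")
    return out
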