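"""Threshold-parameter segmentation and percent density.

Threshold-based labeling tools expose two knobs: a brightness corrector
``alpha_bright`` applied multiplicatively to the normalized image, and a
fibroglandular threshold ``th_f`` above which a (corrected) pixel counts as
dense tissue.  Reconstructing a mask from ``(alpha_bright, th_f)`` is the
bridge between the networks' parameter branch and such tools: a user can
load the predicted parameters and fine-tune them interactively.

The exact rule is isolated here so an alternative correction (additive,
gamma) would be a one-line swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyBreast, InvalidParams, ShapeMismatch
from .preprocessing import BreastMask, NormalizedImage

__all__ = ["SegmentationParams", "DenseMask", "reconstruct_mask",
           "soft_reconstruct", "percent_density", "ALPHA_BOX", "SOFT_STEEPNESS"]

ALPHA_BOX = (0.0, 4.0)      # alpha_bright in (0, 4]
SOFT_STEEPNESS = 50.0       # default sigmoid steepness for the soft mask


@dataclass
class SegmentationParams:
    """The two threshold-tool parameters.

    ``alpha_bright`` — multiplicative brightness corrector, in (0, 4].
    ``th_f`` — fibroglandular threshold on the corrected intensity, in [0, 1].
    """

    alpha_bright: float
    th_f: float

    def validate(self) -> None:
        lo, hi = ALPHA_BOX
        if not (np.isfinite(self.alpha_bright) and lo < self.alpha_bright <= hi):
            raise InvalidParams(f"alpha_bright {self.alpha_bright} outside ({lo}, {hi}]")
        if not (np.isfinite(self.th_f) and 0.0 <= self.th_f <= 1.0):
            raise InvalidParams(f"th_f {self.th_f} outside [0, 1]")

    def to_dict(self) -> dict:
        return {"alpha": float(self.alpha_bright), "th_f": float(self.th_f)}

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        return cls(float(d["alpha"]), float(d["th_f"]))


@dataclass
class DenseMask:
    mask: np.ndarray
    source: str = "parametric"   # parametric | network | annotator

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


def reconstruct_mask(image: NormalizedImage, params: SegmentationParams) -> DenseMask:
    """Hard parametric segmentation.

    Corrected intensity ``I' = clip(alpha_bright * I, 0, 1)`` on breast
    pixels; a pixel is dense iff ``I' >= th_f`` (ties count as dense) and it
    lies inside the breast mask.
    """
    params.validate()
    corrected = np.clip(params.alpha_bright * image.pixels, 0.0, 1.0)
    dense = (corrected >= params.th_f) & image.breast_mask.mask
    return DenseMask(dense, source="parametric")


def soft_reconstruct(image: NormalizedImage, params: SegmentationParams,
                     steepness: float = SOFT_STEEPNESS) -> np.ndarray:
    """Differentiable relaxation: ``sigmoid(k * (I' - th_f))`` on the breast,
    0 outside.  Converges pixel-wise to the hard mask as ``k`` grows (except
    exactly at ``I' == th_f``).  Used only for gradient flow in the
    parametric loss, never for reported masks."""
    params.validate()
    if steepness <= 0:
        raise InvalidParams("steepness must be positive")
    corrected = np.clip(params.alpha_bright * image.pixels, 0.0, 1.0)
    z = np.clip(steepness * (corrected - params.th_f), -60, 60)
    p = 1.0 / (1.0 + np.exp(-z))
    return p * image.breast_mask.mask


def percent_density(dense: DenseMask, breast: BreastMask) -> float:
    """Fraction of breast pixels labeled dense: ``|dense| / |breast|``."""
    if dense.mask.shape != breast.mask.shape:
        raise ShapeMismatch("dense and breast masks differ in shape")
    n_breast = int(breast.mask.sum())
    if n_breast == 0:
        raise EmptyBreast("percent density undefined for an empty breast mask")
    return float((dense.mask & breast.mask).sum()) / n_breast
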