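"""Synthetic mammogram phantoms with known ground truth.

The generator emulates the geometry a left-oriented screening mammogram
presents to the pipeline: a dark background, a half-elliptical breast
attached to the left image border at a fatty-tissue base intensity, an
optional bright pectoral triangle in the top-left corner (MLO view), and
dense tissue formed as a union of Gaussian blobs thresholded at half
maximum, whose intensity lift makes them brighter than the fatty base.
Blob sizes are solved from the requested percent density and resampled
until the realized PD lands within +-0.05 of the target.

Simulated annotators corrupt the true dense mask in the two ways real
experts disagree: systematically (a threshold-tool reading with their own
brightness/threshold settings) or stochastically (per-pixel label flips,
optionally concentrated within a few pixels of the true boundary, where
inter-reader disagreement actually happens).

Every operation takes an explicit seed; all per-image randomness derives
from the top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import UnsatisfiableSpec
from .parametric import DenseMask, SegmentationParams, reconstruct_mask
from .preprocessing import BreastMask, NormalizedImage, RawMammogram
from .training import Sample

__all__ = ["PhantomSpec", "AnnotatorSpec", "generate_phantom",
           "simulate_annotator", "generate_dataset", "phantom_to_sample",
           "OVER_SEGMENTER", "UNDER_SEGMENTER"]

GRAY_MAX = 65535.0          # phantoms are quantized to 16-bit levels
BACKGROUND_LEVEL = 0.02
BREAST_BASE = 0.30
PECTORAL_LEVEL = 0.75       # brightest structure: its border dominates the
                            # horizontal gradient everywhere in the left half
HALF_MAX_FACTOR = np.sqrt(2.0 * np.log(2.0))   # half-max radius = 1.177 sigma


@dataclass
class PhantomSpec:
    size: tuple[int, int] = (128, 128)
    view: str = "CC"                       # CC | MLO
    target_pd: float = 0.18
    n_blobs: int = 4
    blob_contrast: float = 0.35
    noise_sd: float = 0.02
    pectoral: bool | None = None           # default: view == "MLO"
    triangle_frac: tuple[float, float] = (0.35, 0.40)  # (top width, left height)
    seed: int = 0

    def __post_init__(self):
        if not 0.05 <= self.target_pd <= 0.5:
            raise ValueError("target_pd must lie in [0.05, 0.5]")
        if self.pectoral is None:
            self.pectoral = self.view == "MLO"


@dataclass
class AnnotatorSpec:
    """How a simulated expert corrupts the truth.

    ``threshold`` mode reads the image with its own ``(alpha_r, th_f_r)``
    (systematic, deterministic bias).  ``confusion`` mode flips labels with
    ``p_fp = P(says dense | true background)`` and ``p_fn = P(says
    background | true dense)``; with ``boundary_weighting`` the flips are
    confined to within ``boundary_px`` pixels of the true mask boundary.
    """

    mode: str = "confusion"
    alpha_r: float = 1.0
    th_f_r: float = 0.5
    p_fp: float = 0.0
    p_fn: float = 0.0
    boundary_weighting: bool = True
    boundary_px: int = 3

    def __post_init__(self):
        if self.mode not in ("threshold", "confusion"):
            raise ValueError("mode must be 'threshold' or 'confusion'")
        if not (0 <= self.p_fp <= 1 and 0 <= self.p_fn <= 1):
            raise ValueError("flip probabilities must be in [0, 1]")


# the canonical biased pair used throughout the tests: annotator 1
# over-segments (adds dense near the boundary), annotator 2 under-segments
OVER_SEGMENTER = AnnotatorSpec(mode="confusion", p_fp=0.25, p_fn=0.0)
UNDER_SEGMENTER = AnnotatorSpec(mode="confusion", p_fp=0.0, p_fn=0.25)


def _breast_ellipse(H: int, W: int) -> np.ndarray:
    rr, cc = np.mgrid[0:H, 0:W]
    ry, rx = 0.45 * H, 0.55 * W
    return ((rr - H / 2.0) / ry) ** 2 + (cc / rx) ** 2 <= 1.0


def _pectoral_triangle(H: int, W: int, frac: tuple[float, float]) -> np.ndarray:
    c_top, r_bot = frac[0] * W, frac[1] * H
    rr, cc = np.mgrid[0:H, 0:W]
    return (cc / c_top + rr / r_bot) <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(RawMammogram, true_breast, true_dense, geometry)`` where the
    masks are ground truth and ``geometry`` records the ellipse, triangle
    and blob parameters used."""
    H, W = spec.size
    if spec.n_blobs < 1:
        raise ValueError("need at least one dense blob")
    rng = np.random.default_rng(spec.seed)
    ellipse = _breast_ellipse(H, W)
    triangle = (_pectoral_triangle(H, W, spec.triangle_frac)
                if spec.pectoral else np.zeros((H, W), bool))
    true_breast = ellipse & ~triangle
    breast_area = int(true_breast.sum())

    # solve the per-blob scale from the PD target, then jitter and resample
    target_area = spec.target_pd * breast_area
    sigma0 = np.sqrt(target_area / (spec.n_blobs * np.pi)) / HALF_MAX_FACTOR
    rr, cc = np.mgrid[0:H, 0:W]
    interior = ndi.binary_erosion(true_breast,
                                  iterations=max(1, int(sigma0)))
    if not interior.any():
        interior = true_breast
    cand_r, cand_c = np.nonzero(interior)

    dense = field_total = None
    for _ in range(100):
        idx = rng.integers(0, len(cand_r), size=spec.n_blobs)
        sigmas = sigma0 * rng.uniform(0.8, 1.2, size=spec.n_blobs)
        field_total = np.zeros((H, W))
        for k in range(spec.n_blobs):
            d2 = (rr - cand_r[idx[k]]) ** 2 + (cc - cand_c[idx[k]]) ** 2
            np.maximum(field_total, np.exp(-d2 / (2.0 * sigmas[k] ** 2)),
                       out=field_total)
        cand_dense = (field_total >= 0.5) & true_breast
        pd_realized = cand_dense.sum() / breast_area
        if abs(pd_realized - spec.target_pd) <= 0.05:
            dense = cand_dense
            break
    if dense is None:
        raise UnsatisfiableSpec(
            f"could not realize PD {spec.target_pd} within 100 attempts")

    img = np.full((H, W), BACKGROUND_LEVEL)
    img[ellipse] = BREAST_BASE
    img[ellipse & triangle] = PECTORAL_LEVEL
    if spec.pectoral:
        img[triangle] = PECTORAL_LEVEL       # muscle fills the full corner
    img += spec.blob_contrast * field_total * true_breast
    img += rng.normal(0.0, spec.noise_sd, size=(H, W))
    img = np.round(np.clip(img, 0.0, 1.0) * GRAY_MAX)

    geometry = {
        "ellipse": {"ry": 0.45 * H, "rx": 0.55 * W, "center_row": H / 2.0},
        "triangle": {"present": bool(spec.pectoral),
                     "c_top": spec.triangle_frac[0] * W,
                     "r_bot": spec.triangle_frac[1] * H},
        "blobs": {"rows": cand_r[idx].tolist(), "cols": cand_c[idx].tolist(),
                  "sigmas": sigmas.tolist()},
        "pd_realized": float(dense.sum() / breast_area),
    }
    raw = RawMammogram(img, view=spec.view)
    return (raw, BreastMask(true_breast, float("nan")),
            DenseMask(dense, source="annotator"), geometry)


def simulate_annotator(true_dense: DenseMask, true_breast: BreastMask,
                       image: RawMammogram, spec: AnnotatorSpec,
                       seed: int) -> np.ndarray:
    """Produce one noisy expert mask for a phantom."""
    breast = true_breast.mask
    if spec.mode == "threshold":
        norm = NormalizedImage(image.pixels / GRAY_MAX, true_breast)
        params = SegmentationParams(spec.alpha_r, spec.th_f_r)
        return reconstruct_mask(norm, params).mask & breast
    rng = np.random.default_rng(seed)
    truth = true_dense.mask & breast
    out = truth.copy()
    if spec.boundary_weighting:
        dil = ndi.binary_dilation(truth, iterations=spec.boundary_px)
        ero = ndi.binary_erosion(truth, iterations=spec.boundary_px)
        band = dil & ~ero
    else:
        band = np.ones_like(truth)
    flips = rng.random(truth.shape)
    fp = (~truth) & breast & band & (flips < spec.p_fp)
    fn = truth & band & (flips < spec.p_fn)
    out[fp] = True
    out[fn] = False
    return out


def phantom_to_sample(spec: PhantomSpec, annotator_specs: list[AnnotatorSpec],
                      seed: int, patient_id: str = "", sample_id: str = "",
                      center_id: str = "") -> Sample:
    """Render a phantom and its annotations directly as a training sample.

    The network input is the phantom intensity rescaled to [0, 1] with the
    background zeroed — the phantom is generated already histogram-tame, so
    the classical normalization is exercised separately on the raw image."""
    pspec = PhantomSpec(**{**spec.__dict__, "seed": seed})
    raw, breast, dense, _ = generate_phantom(pspec)
    sub = np.random.SeedSequence(seed).generate_state(len(annotator_specs) + 1)
    annotations = [simulate_annotator(dense, breast, raw, a,
                                      int(sub[i + 1] % (2 ** 31)))
                   for i, a in enumerate(annotator_specs)]
    img = (raw.pixels / GRAY_MAX) * breast.mask
    return Sample(image=img, breast=breast.mask, annotations=annotations,
                  patient_id=patient_id, sample_id=sample_id,
                  true_dense=dense.mask, center_id=center_id)


def generate_dataset(n_images: int, phantom_spec: PhantomSpec,
                     annotator_specs: list[AnnotatorSpec], seed: int,
                     out_dir: str | Path | None = None
                     ) -> tuple[list[Sample], pd.DataFrame]:
    """A training-ready phantom corpus.

    Two images share each synthetic patient id so grouped splitting is
    exercised.  With ``out_dir`` the images (16-bit PNG), annotator masks and
    ground-truth masks are written to disk along with a manifest CSV."""
    if n_images < 1:
        raise ValueError("need n_images >= 1")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2 ** 31, size=n_images)
    samples, rows = [], []
    for i in range(n_images):
        pid = f"P{i // 2:04d}"
        sid = f"S{i:04d}"
        s = phantom_to_sample(phantom_spec, annotator_specs, int(seeds[i]),
                              patient_id=pid, sample_id=sid, center_id="SYN")
        samples.append(s)
        rows.append({"sample_id": sid, "patient_id": pid, "center_id": "SYN",
                     "view": phantom_spec.view, "seed": int(seeds[i])})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from . import io as mio
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s, row in zip(samples, rows):
            sid = row["sample_id"]
            mio.write_image_png(out_dir / f"{sid}.png",
                                np.round(s.image * GRAY_MAX))
            mio.write_mask_png(out_dir / f"{sid}_breast.png", s.breast)
            mio.write_mask_png(out_dir / f"{sid}_truth.png", s.true_dense)
            for r, a in enumerate(s.annotations):
                mio.write_mask_png(out_dir / f"{sid}_r{r + 1}.png", a)
            row["image_path"] = f"{sid}.png"
            for r in range(len(s.annotations)):
                row[f"annotator_{r + 1}"] = f"{sid}_r{r + 1}.png"
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return samples, manifest
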