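"""Classical mammogram preprocessing.

Turns a raw "for presentation" mammogram into the network input: a
left-oriented, breast-only image with the pectoral muscle excluded and
intensities normalized to [0, 1] by a fixed seven-step histogram protocol.
Acquisition devices differ wildly in their display histograms; the protocol
removes gain/offset differences and stretches the intensity band where the
fatty/dense transition lives, so that a single model can serve many devices.

Coordinates are row-major, origin top-left, ``(row, col)``, 0-based.  Masks
are boolean arrays with ``True`` = tissue of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import measure as skmeasure

from .errors import DegenerateHistogram, NoThresholdFound, ShapeMismatch

__all__ = [
    "RawMammogram", "BreastMask", "ExclusionPolygon", "NormalizedImage",
    "orient_left", "detect_breast", "exclude_pectoral", "normalize_histogram",
    "preprocess",
]

# Candidate-threshold cap for breast detection: scanning every unique gray
# value is quadratic on 16-bit inputs; rank-subsampling preserves the
# monotone-relabeling invariance because only the order of values matters.
MAX_THRESHOLD_CANDIDATES = 256

# Pectoral-exclusion constants, stated for full-resolution (~1024+ px) images
# and scaled down linearly with image height below that.
PECTORAL_SIGMA = 3.0
PECTORAL_WINDOW = 50
PECTORAL_ROW_STEP = 50
PECTORAL_MIN_ROW_STEP = 8
PECTORAL_REFERENCE_HEIGHT = 1024
PECTORAL_EDGE_EPS = 5          # "close enough to the left border", columns
PECTORAL_GRADIENT_FLOOR = 0.10  # fraction of the image's gray-level range


@dataclass
class RawMammogram:
    """A raw grayscale mammogram.

    Attributes
    ----------
    pixels
        2-D array of non-negative gray levels (any bit depth).
    pixel_spacing
        Optional (row, col) physical spacing in mm.
    view
        ``"CC"``, ``"MLO"`` or ``"unknown"``.
    flipped
        True when :func:`orient_left` mirrored the image; predictions must be
        mirrored back before writing.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    view: str = "unknown"
    flipped: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ShapeMismatch("mammogram must be a 2-D grayscale image")
        if min(self.pixels.shape) < 64:
            raise ValueError("image too small: height and width must be >= 64")


@dataclass
class BreastMask:
    mask: np.ndarray
    breast_threshold: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class ExclusionPolygon:
    """Ordered (row, col) vertices enclosing the pectoral/armpit region."""

    vertices: list[tuple[int, int]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.vertices) < 3

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean interior (including edge pixels) of the closed polygon."""
        if self.empty:
            return np.zeros(shape, dtype=bool)
        rows = np.array([v[0] for v in self.vertices], dtype=float)
        cols = np.array([v[1] for v in self.vertices], dtype=float)
        rr, cc = skdraw.polygon(rows, cols, shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        rr, cc = skdraw.polygon_perimeter(rows, cols, shape=shape)
        out[rr, cc] = True
        return out


@dataclass
class NormalizedImage:
    """Network input: breast-only intensities in [0,1], background zeroed."""

    pixels: np.ndarray
    breast_mask: BreastMask
    flipped: bool = False


def orient_left(image: RawMammogram) -> RawMammogram:
    """Mirror the image horizontally if the breast sits in the right half.

    The decision compares summed intensity of the two halves; ties count as
    already left-oriented.  Idempotent.
    """
    px = image.pixels
    w = px.shape[1]
    left = px[:, : w // 2].sum()
    right = px[:, w - w // 2:].sum()
    if right > left:
        return RawMammogram(px[:, ::-1].copy(), image.pixel_spacing,
                            image.view, flipped=not image.flipped)
    return image


def _count_components(binary: np.ndarray) -> int:
    """Number of 8-connected components counting both phases of the image."""
    n_fg = skmeasure.label(binary, connectivity=2).max()
    n_bg = skmeasure.label(~binary, connectivity=2).max()
    return int(n_fg) + int(n_bg)


def detect_breast(image: RawMammogram) -> BreastMask:
    """Separate breast from background by iterative threshold search.

    The most frequent gray value is assumed to belong to the background.
    Candidate thresholds are the unique gray values strictly above that mode,
    scanned in ascending order; the first threshold whose binarization yields
    exactly two homogeneous 8-connected components (one background, one
    breast) wins.  If no candidate yields exactly two, the best candidate
    (closest to two components) is used and a warning is emitted.
    """
    px = image.pixels
    values, counts = np.unique(px, return_counts=True)
    if values.size < 2:
        raise NoThresholdFound("constant image: no breast/background contrast")
    mode = values[np.argmax(counts)]
    candidates = values[values > mode]
    if candidates.size == 0:
        raise NoThresholdFound("modal gray value is the image maximum")
    if candidates.size > MAX_THRESHOLD_CANDIDATES:
        # Thresholding anywhere inside a gap between consecutive unique
        # values equals thresholding at the upper value, so a value-spaced
        # grid snapped up to the next unique value loses nothing essential
        # while bridging empty gray-level gaps (e.g. background vs breast).
        idx = np.linspace(0, candidates.size - 1,
                          MAX_THRESHOLD_CANDIDATES).astype(int)
        grid = np.linspace(candidates[0], candidates[-1],
                           MAX_THRESHOLD_CANDIDATES)
        snapped = np.searchsorted(candidates, grid, side="left")
        snapped = np.clip(snapped, 0, candidates.size - 1)
        candidates = np.unique(np.concatenate([candidates[idx],
                                               candidates[snapped]]))

    best_t, best_err = None, None
    for t in candidates:
        binary = px >= t
        n = _count_components(binary)
        if n == 2:
            return BreastMask(binary, float(t))
        err = abs(n - 2)
        if best_err is None or err < best_err:
            best_t, best_err = t, err
    warnings.warn("no threshold produced exactly two components; "
                  f"using best candidate {best_t!r}")
    return BreastMask(px >= best_t, float(best_t))


def _pectoral_scales(height: int) -> tuple[float, int, int]:
    """(sigma, window, row_step) scaled to the image height."""
    f = min(1.0, height / PECTORAL_REFERENCE_HEIGHT)
    sigma = PECTORAL_SIGMA * f
    window = max(3, int(round(PECTORAL_WINDOW * f)))
    row_step = max(PECTORAL_MIN_ROW_STEP, int(round(PECTORAL_ROW_STEP * f)))
    return sigma, window, row_step


def exclude_pectoral(image: RawMammogram, mask: BreastMask) -> ExclusionPolygon:
    """Build a polygon enclosing the pectoral muscle and remove it from the mask.

    On MLO views the muscle appears as a bright triangle in the top-left
    corner (the image being left-oriented).  The border is found by tracking,
    every ``row_step`` rows from the top, the column with the most negative
    horizontal gradient of the smoothed image; tracking stops when the border
    reaches the left edge.  The polygon is closed at the top-left corner and
    its interior is removed from ``mask`` in place.

    Returns an empty polygon (mask untouched) when the first sampled row has
    no gradient dip below the floor — the CC-view case.
    """
    px = image.pixels
    H, W = px.shape
    sigma, window, row_step = _pectoral_scales(H)
    smooth = ndi.gaussian_filter(px, sigma=sigma)
    smooth = ndi.uniform_filter1d(smooth, size=window, axis=1)
    # gradient over the moving window (value ahead minus value behind): for
    # an edge this approaches the full intensity drop, making the 10%-of-
    # range floor meaningful at any resolution
    half = max(1, window // 2)
    ahead = np.empty_like(smooth)
    behind = np.empty_like(smooth)
    ahead[:, :-half] = smooth[:, half:]
    ahead[:, -half:] = smooth[:, -1:]
    behind[:, half:] = smooth[:, :-half]
    behind[:, :half] = smooth[:, :1]
    grad = ahead - behind
    floor = PECTORAL_GRADIENT_FLOOR * (px.max() - px.min())

    half_w = W // 2
    verts: list[tuple[int, int]] = [(0, 0)]
    limit = half_w   # the muscle border moves monotonically toward col 0
    for row in range(0, H // 2, row_step):
        row_grad = grad[row, :limit]
        if row_grad.size == 0:
            break
        col = int(np.argmin(row_grad))
        if row_grad[col] > -floor:
            if row == 0:
                return ExclusionPolygon([])   # no muscle edge: CC view
            break
        verts.append((row, col))
        if col <= PECTORAL_EDGE_EPS:
            break
        limit = col + 1
    if len(verts) < 3:
        return ExclusionPolygon([])
    if verts[-1][1] > 0:
        verts.append((verts[-1][0], 0))   # close along the left border
    poly = ExclusionPolygon(verts)
    mask.mask &= ~poly.rasterize(px.shape)
    return poly


def _breast_mode(values: np.ndarray, bins: int = 256) -> float:
    """Mode of a continuous sample: center of the fullest histogram bin."""
    hist, edges = np.histogram(values, bins=bins)
    i = int(np.argmax(hist))  # argmax takes the lowest bin on ties
    return 0.5 * (edges[i] + edges[i + 1])


def normalize_histogram(image: RawMammogram, mask: BreastMask,
                        return_steps: bool = False) -> NormalizedImage:
    """Apply the seven-step histogram normalization over breast pixels.

    1. rescale the whole image to [0, 1];
    2. shift so the minimum breast pixel is 0;
    3. rescale breast values to [0, 1];
    4. z-standardize breast values;
    5. shift so the modal breast value is 0 (256-bin histogram mode);
    6. piecewise-linear stretch mapping the 30th percentile to -1 and the
       70th percentile to +1 (unit slope outside the anchors);
    7. final min-max rescale to [0, 1].

    Background (non-breast) pixels are set to 0.  With ``return_steps`` the
    per-step breast-pixel vectors are returned alongside for verification.
    """
    b = mask.mask
    if b.shape != image.pixels.shape:
        raise ShapeMismatch("mask and image shapes differ")
    if not b.any():
        raise DegenerateHistogram("empty breast mask")
    px = image.pixels
    lo, hi = px.min(), px.max()
    if hi == lo:
        raise DegenerateHistogram("constant image")
    steps: list[np.ndarray] = []
    v = (px[b] - lo) / (hi - lo)                      # step 1
    steps.append(v)
    v = v - v.min()                                   # step 2
    steps.append(v)
    if v.max() == 0:
        raise DegenerateHistogram("constant breast intensities")
    v = v / v.max()                                   # step 3
    steps.append(v)
    sd = v.std()
    if sd == 0:
        raise DegenerateHistogram("constant breast intensities")
    v = (v - v.mean()) / sd                           # step 4
    steps.append(v)
    v = v - _breast_mode(v)                           # step 5
    steps.append(v)
    p30, p70 = np.percentile(v, [30.0, 70.0])
    if p30 == p70:
        raise DegenerateHistogram("stretch anchors coincide (p30 == p70)")
    v = _stretch(v, p30, p70)                         # step 6
    steps.append(v)
    v = (v - v.min()) / (v.max() - v.min())           # step 7
    steps.append(v)

    out = np.zeros_like(px, dtype=np.float64)
    out[b] = v
    norm = NormalizedImage(out, mask, flipped=image.flipped)
    if return_steps:
        return norm, steps
    return norm


def _stretch(v: np.ndarray, p30: float, p70: float) -> np.ndarray:
    """Three-segment monotone map: anchors (p30, -1) and (p70, +1).

    The middle segment carries slope 2/(p70-p30); the outer segments continue
    with unit slope so the map stays strictly monotone for any anchors.
    """
    mid_slope = 2.0 / (p70 - p30)
    out = np.empty_like(v)
    below = v < p30
    above = v > p70
    mid = ~(below | above)
    out[below] = -1.0 + (v[below] - p30)
    out[mid] = -1.0 + mid_slope * (v[mid] - p30)
    out[above] = 1.0 + (v[above] - p70)
    return out


def preprocess(image: RawMammogram, pectoral: bool = True) -> NormalizedImage:
    """Full classical pipeline: orient, detect breast, exclude pectoral,
    normalize.  Normalization statistics are computed on the post-exclusion
    breast region."""
    image = orient_left(image)
    mask = detect_breast(image)
    if pectoral:
        exclude_pectoral(image, mask)
    return normalize_histogram(image, mask)
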