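"""Contour extraction for optic-disc/cup structure.

The chain is the classical Canny recipe spelled out stage by stage:
grayscale conversion, Gaussian smoothing, Sobel gradients, non-maximum
suppression along the quantized gradient direction, double thresholding
relative to the maximum gradient magnitude, and eight-connected hysteresis
tracking.  On top of the binary contour map sit two diagnostic localizers:
a circular-Hough optic-disc finder and an intensity-based optic-cup
segmenter that reports the cup-to-disc ratio (CDR).

Implementation notes that double as the module's numerical contract:

* Convolutions accumulate kernel taps in row-major order over a
  reflect-padded image, so each output pixel is built by the exact same
  IEEE-754 operation sequence as a naive per-pixel loop.
* The gradient direction is quantized to four bins (0, 45, 90, 135 degrees)
  directly from ``(gx, gy)`` by sign and slope comparisons against
  ``tan(22.5deg)`` and ``tan(67.5deg)``; no trigonometry is involved, so the
  binning is exact.  The ``direction`` field of :class:`GradientField` (in
  degrees, folded to ``[0, 180)``) is diagnostic.
* Non-maximum suppression keeps ties (``>=`` against both neighbours);
  out-of-frame neighbours count as zero magnitude.
* A pixel exactly at ``high * max`` is strong (inclusive high threshold).
  An all-zero magnitude map yields an empty contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import hough_circle

from .phantom import LabeledImage

LUMA_WEIGHTS = (0.299, 0.587, 0.114)
_TAN_22_5 = math.sqrt(2.0) - 1.0
_TAN_67_5 = math.sqrt(2.0) + 1.0


class ContourParamError(ValueError):
    pass


class DiscNotFoundError(RuntimeError):
    """No circular disc candidate: the edge map was empty."""


def default_sigma(kernel: int) -> float:
    """Gaussian sigma tied to kernel size: ``0.3 * ((k - 1) / 2 - 1) + 0.8``."""
    return 0.3 * ((kernel - 1) / 2.0 - 1.0) + 0.8


@dataclass(frozen=True)
class ContourParams:
    """Smoothing and threshold settings of the contour chain.

    ``low_threshold`` / ``high_threshold`` are fractions of the maximum
    gradient magnitude after non-maximum suppression.
    """

    gaussian_kernel: int = 5
    gaussian_sigma: float | None = None
    low_threshold: float = 0.10
    high_threshold: float = 0.30

    def __post_init__(self) -> None:
        if self.gaussian_kernel < 3 or self.gaussian_kernel % 2 == 0:
            raise ContourParamError("gaussian_kernel must be an odd integer >= 3")
        sigma = self.sigma
        if sigma <= 0:
            raise ContourParamError("gaussian_sigma must be > 0")
        if not 0.0 < self.low_threshold < self.high_threshold:
            raise ContourParamError("thresholds must satisfy 0 < low < high")

    @property
    def sigma(self) -> float:
        return self.gaussian_sigma if self.gaussian_sigma is not None else default_sigma(self.gaussian_kernel)


@dataclass
class GradientField:
    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray  # degrees, folded to [0, 180)


@dataclass
class ContourMap:
    edges: np.ndarray  # (H, W) bool
    params: ContourParams


@dataclass
class DiscLocation:
    center: tuple[int, int]  # (row, col)
    radius: int
    accumulator_score: float


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Luma conversion (0.299 R + 0.587 G + 0.114 B), values in [0, 255]."""
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    p = pixels.astype(np.float64)
    wr, wg, wb = LUMA_WEIGHTS
    return wr * p[:, :, 0] + wg * p[:, :, 1] + wb * p[:, :, 2]


def gaussian_kernel_2d(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel; weights sum to 1.

    The normalizing sum is accumulated element by element in row-major order
    so the kernel is reproducible by scalar arithmetic.
    """
    if size % 2 == 0 or size < 3:
        raise ContourParamError("kernel size must be odd and >= 3")
    c = (size - 1) // 2
    kern = np.empty((size, size), dtype=np.float64)
    for i in range(size):
        for j in range(size):
            kern[i, j] = math.exp(-((i - c) ** 2 + (j - c) ** 2) / (2.0 * sigma * sigma))
    total = 0.0
    for i in range(size):
        for j in range(size):
            total += kern[i, j]
    return kern / total


def _convolve_reflect(grid: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Correlate with reflect (mirror, edge not repeated) border handling.

    Kernel taps are accumulated in row-major order, matching a per-pixel
    nested loop operation for operation.
    """
    k = kern.shape[0]
    pad = k // 2
    if grid.shape[0] <= pad or grid.shape[1] <= pad:
        raise ValueError("image too small for the requested kernel")
    padded = np.pad(grid, pad, mode="reflect")
    h, w = grid.shape
    out = np.zeros((h, w), dtype=np.float64)
    for di in range(k):
        for dj in range(k):
            out += kern[di, dj] * padded[di : di + h, dj : dj + w]
    return out


def gaussian_blur(gray: np.ndarray, params: ContourParams) -> np.ndarray:
    kern = gaussian_kernel_2d(params.gaussian_kernel, params.sigma)
    return _convolve_reflect(gray, kern)


SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = np.array([[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]])


def sobel_gradients(smoothed: np.ndarray) -> GradientField:
    """3x3 Sobel derivatives, gradient magnitude and folded direction."""
    if smoothed.shape[0] < 3 or smoothed.shape[1] < 3:
        raise ValueError("image must be at least 3 x 3 for Sobel gradients")
    gx = _convolve_reflect(smoothed, SOBEL_X)
    gy = _convolve_reflect(smoothed, SOBEL_Y)
    magnitude = np.sqrt(gx * gx + gy * gy)
    direction = np.degrees(np.arctan2(gy, gx))
    direction = np.where(direction < 0.0, direction + 180.0, direction)
    direction = np.where(direction >= 180.0, direction - 180.0, direction)
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, direction=direction)


def quantize_direction(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Gradient direction quantized to bins 0/1/2/3 = 0/45/90/135 degrees.

    Purely comparison-based: ``|gy| <= tan(22.5) |gx|`` is horizontal-ish
    (bin 0), ``|gy| >= tan(67.5) |gx|`` vertical-ish (bin 2); otherwise the
    diagonal bin follows the sign of ``gx * gy``.
    """
    ax = np.abs(gx)
    ay = np.abs(gy)
    bins = np.full(gx.shape, 3, dtype=np.int8)
    bins[(gx * gy) > 0.0] = 1
    bins[ay >= _TAN_67_5 * ax] = 2
    bins[ay <= _TAN_22_5 * ax] = 0
    return bins


# Neighbour offsets (dr, dc) along the gradient for each direction bin.
_NMS_OFFSETS = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}


def non_maximum_suppression(fieldv: GradientField) -> np.ndarray:
    """Keep a pixel's magnitude iff it is >= both neighbours along its
    quantized gradient direction; otherwise reset it to zero."""
    mag = fieldv.magnitude
    h, w = mag.shape
    bins = quantize_direction(fieldv.gx, fieldv.gy)
    padded = np.zeros((h + 2, w + 2), dtype=np.float64)
    padded[1:-1, 1:-1] = mag
    keep = np.zeros((h, w), dtype=bool)
    for b, (dr, dc) in _NMS_OFFSETS.items():
        fwd = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        bwd = padded[1 - dr : 1 - dr + h, 1 - dc : 1 - dc + w]
        sel = bins == b
        keep |= sel & (mag >= fwd) & (mag >= bwd)
    return np.where(keep, mag, 0.0)


# Below this magnitude a "maximum" is numerical residue (the blur of a flat
# region leaves O(1e-13) gradients), not an edge: treat the map as empty.
MIN_MAGNITUDE = 1e-9


def double_threshold(nms: np.ndarray, params: ContourParams) -> tuple[np.ndarray, np.ndarray]:
    """Partition into strong (>= high*max) and weak ([low*max, high*max))."""
    if params.low_threshold >= params.high_threshold:
        raise ContourParamError("low threshold must be < high threshold")
    m = float(np.max(nms)) if nms.size else 0.0
    if m < MIN_MAGNITUDE:
        z = np.zeros(nms.shape, dtype=bool)
        return z, z.copy()
    strong = nms >= params.high_threshold * m
    weak = (nms >= params.low_threshold * m) & ~strong
    return strong, weak


def hysteresis_tracking(strong: np.ndarray, weak: np.ndarray) -> np.ndarray:
    """Strong pixels plus weak pixels 8-connected to a strong pixel through
    weak pixels (transitive closure, breadth-first)."""
    if np.any(strong & weak):
        raise ValueError("strong and weak maps must be disjoint")
    h, w = strong.shape
    out = strong.copy()
    frontier = list(zip(*np.nonzero(strong)))
    weak_left = weak.copy()
    while frontier:
        nxt = []
        for r, c in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and weak_left[rr, cc]:
                        weak_left[rr, cc] = False
                        out[rr, cc] = True
                        nxt.append((rr, cc))
        frontier = nxt
    return out


def extract_contour(image: LabeledImage | np.ndarray, params: ContourParams | None = None) -> ContourMap:
    """Full chain: grayscale -> blur -> Sobel -> NMS -> thresholds -> hysteresis."""
    params = params or ContourParams()
    pixels = image.pixels if isinstance(image, LabeledImage) else image
    gray = to_grayscale(pixels) if pixels.ndim == 3 else pixels.astype(np.float64)
    smoothed = gaussian_blur(gray, params)
    fieldv = sobel_gradients(smoothed)
    nms = non_maximum_suppression(fieldv)
    strong, weak = double_threshold(nms, params)
    edges = hysteresis_tracking(strong, weak)
    return ContourMap(edges=edges, params=params)


def contour_to_image(cm: ContourMap) -> np.ndarray:
    """Binary contour map replicated to a 3-channel 8-bit image so the same
    classifier backbone accepts contours and photographs alike."""
    plane = (cm.edges.astype(np.uint8)) * 255
    return np.repeat(plane[:, :, None], 3, axis=2)


def locate_optic_disc(
    image: LabeledImage | np.ndarray,
    radius_range: tuple[int, int],
    params: ContourParams | None = None,
) -> DiscLocation:
    """Circular-Hough disc localization on the contour map.

    Returns the accumulator-maximizing (center, radius); exact ties are
    broken by the smallest (row, col, radius).
    """
    rmin, rmax = radius_range
    cm = extract_contour(image, params)
    h, w = cm.edges.shape
    if not (0 < rmin < rmax) or rmax >= min(h, w) / 2:
        raise ValueError("radius_range must satisfy 0 < rmin < rmax < min(H, W)/2")
    if not np.any(cm.edges):
        raise DiscNotFoundError("edge map is empty; no disc candidate")
    # Raw (unnormalized) votes: a full circle scores ~its circumference, so
    # the outer disc ring dominates the inner cup ring when both are present.
    radii = np.arange(rmin, rmax + 1)
    accum = hough_circle(cm.edges, radii, normalize=False)
    best = float(np.max(accum))
    ridx, rows, cols = np.nonzero(accum == best)
    order = np.lexsort((radii[ridx], cols, rows))
    k = order[0]
    return DiscLocation(
        center=(int(rows[k]), int(cols[k])), radius=int(radii[ridx[k]]), accumulator_score=best
    )


def locate_optic_cup(
    image: LabeledImage | np.ndarray,
    disc: DiscLocation,
    percentile: float = 70.0,
) -> tuple[np.ndarray, float]:
    """Intensity-based cup segmentation inside the disc ROI.

    The cup on a fundus photograph is brighter than the surrounding disc
    tissue, so the cup mask is the set of ROI pixels whose intensity exceeds
    a cut placed at ``percentile`` percent of the robust ROI intensity range
    (5th to 99.5th intensity percentiles).  An intensity-level cut, rather
    than a rank cut, keeps the estimated cup area proportional to the bright
    core rather than fixed by the percentile itself.  The CDR is
    ``sqrt(cup area / disc area)``.  A uniform ROI degenerates to an empty
    cup (CDR 0, finite by convention).
    """
    if not 50.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (50, 100)")
    if disc.radius < 3:
        raise ValueError("degenerate disc: radius must be >= 3 px")
    pixels = image.pixels if isinstance(image, LabeledImage) else image
    gray = to_grayscale(pixels) if pixels.ndim == 3 else pixels.astype(np.float64)
    h, w = gray.shape
    r0, c0 = disc.center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("disc center outside the image")
    rr, cc = np.mgrid[0:h, 0:w]
    roi = (rr - r0) ** 2 + (cc - c0) ** 2 <= disc.radius**2
    vals = gray[roi]
    lo = float(np.percentile(vals, 5.0))
    hi = float(np.percentile(vals, 99.5))
    threshold = lo + (percentile / 100.0) * (hi - lo)
    cup = roi & (gray > threshold)
    cdr = math.sqrt(cup.sum() / roi.sum())
    return cup, cdr
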