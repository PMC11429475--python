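"""Brute-force validation implementation of the contour chain.

Every stage is written as plain nested Python loops over pixels and kernel
taps, independent of the vectorized production code in
:mod:`glaucovit.contour`.  It exists solely as a cross-check: the test suite
and the acceptance script assert that the production chain is bit-identical
to this one on random images.  It is never used by the production path and
is orders of magnitude slower.

The two implementations share only the documented numerical contract
(reflect borders, row-major tap accumulation, comparison-based direction
bins, tie-keeping >= suppression, inclusive high threshold, eight-connected
hysteresis).
"""

from __future__ import annotations

import math

import numpy as np

_TAN_LO = math.sqrt(2.0) - 1.0
_TAN_HI = math.sqrt(2.0) + 1.0

_SOBEL_X = ((-1.0, 0.0, 1.0), (-2.0, 0.0, 2.0), (-1.0, 0.0, 1.0))
_SOBEL_Y = ((-1.0, -2.0, -1.0), (0.0, 0.0, 0.0), (1.0, 2.0, 1.0))


def naive_grayscale(pixels):
    h, w = pixels.shape[0], pixels.shape[1]
    out = np.empty((h, w), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            out[r, c] = (
                0.299 * float(pixels[r, c, 0])
                + 0.587 * float(pixels[r, c, 1])
                + 0.114 * float(pixels[r, c, 2])
            )
    return out


def _reflect(i: int, n: int) -> int:
    # mirror without repeating the edge sample, as numpy's "reflect" mode
    if i < 0:
        return -i
    if i >= n:
        return 2 * n - 2 - i
    return i


def naive_gaussian_kernel(size: int, sigma: float):
    c = (size - 1) // 2
    kern = [[0.0] * size for _ in range(size)]
    for i in range(size):
        for j in range(size):
            kern[i][j] = math.exp(-((i - c) ** 2 + (j - c) ** 2) / (2.0 * sigma * sigma))
    total = 0.0
    for i in range(size):
        for j in range(size):
            total += kern[i][j]
    for i in range(size):
        for j in range(size):
            kern[i][j] = kern[i][j] / total
    return kern


def _naive_correlate(grid, kern, k: int):
    h, w = grid.shape
    pad = k // 2
    out = np.empty((h, w), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for di in range(k):
                for dj in range(k):
                    rr = _reflect(r + di - pad, h)
                    cc = _reflect(c + dj - pad, w)
                    acc += kern[di][dj] * grid[rr, cc]
            out[r, c] = acc
    return out


def naive_blur(gray, kernel_size: int, sigma: float):
    return _naive_correlate(gray, naive_gaussian_kernel(kernel_size, sigma), kernel_size)


def naive_sobel(smoothed):
    gx = _naive_correlate(smoothed, _SOBEL_X, 3)
    gy = _naive_correlate(smoothed, _SOBEL_Y, 3)
    h, w = smoothed.shape
    mag = np.empty((h, w), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            mag[r, c] = math.sqrt(gx[r, c] * gx[r, c] + gy[r, c] * gy[r, c])
    return gx, gy, mag


def _naive_bin(gx: float, gy: float) -> int:
    ax = abs(gx)
    ay = abs(gy)
    if ay <= _TAN_LO * ax:
        return 0
    if ay >= _TAN_HI * ax:
        return 2
    return 1 if gx * gy > 0.0 else 3

_OFFSETS = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}


def naive_nms(gx, gy, mag):
    h, w = mag.shape
    out = np.zeros((h, w), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            dr, dc = _OFFSETS[_naive_bin(gx[r, c], gy[r, c])]
            m = mag[r, c]
            n1 = mag[r + dr, c + dc] if 0 <= r + dr < h and 0 <= c + dc < w else 0.0
            n2 = mag[r - dr, c - dc] if 0 <= r - dr < h and 0 <= c - dc < w else 0.0
            if m >= n1 and m >= n2:
                out[r, c] = m
    return out


def naive_double_threshold(nms, low: float, high: float):
    h, w = nms.shape
    m = 0.0
    for r in range(h):
        for c in range(w):
            if nms[r, c] > m:
                m = nms[r, c]
    strong = np.zeros((h, w), dtype=bool)
    weak = np.zeros((h, w), dtype=bool)
    if m < 1e-9:  # numerical residue, not an edge
        return strong, weak
    for r in range(h):
        for c in range(w):
            v = nms[r, c]
            if v >= high * m:
                strong[r, c] = True
            elif v >= low * m:
                weak[r, c] = True
    return strong, weak


def naive_hysteresis(strong, weak):
    h, w = strong.shape
    out = strong.copy()
    weak = weak.copy()
    queue = [(r, c) for r in range(h) for c in range(w) if strong[r, c]]
    while queue:
        r, c = queue.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and weak[rr, cc]:
                    weak[rr, cc] = False
                    out[rr, cc] = True
                    queue.append((rr, cc))
    return out


def naive_contour_chain(pixels, kernel_size: int = 5, sigma: float | None = None,
                        low: float = 0.10, high: float = 0.30):
    """The full six-stage chain, end to end, in loop form."""
    if sigma is None:
        sigma = 0.3 * ((kernel_size - 1) / 2.0 - 1.0) + 0.8
    gray = naive_grayscale(pixels) if pixels.ndim == 3 else pixels.astype(np.float64)
    smoothed = naive_blur(gray, kernel_size, sigma)
    gx, gy, mag = naive_sobel(smoothed)
    nms = naive_nms(gx, gy, mag)
    strong, weak = naive_double_threshold(nms, low, high)
    return naive_hysteresis(strong, weak)
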