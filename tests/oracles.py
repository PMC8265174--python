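"""Independent brute-force oracles used by the test suite.

These are deliberately written without reusing any package internals:
the rolling-ball oracle is a direct double-loop evaluation of the
erosion/dilation definition, and the Dice oracle works on explicit
coordinate sets.
"""

from __future__ import annotations

import numpy as np


def brute_force_rolling_ball_background(img: np.ndarray, radius: int) -> np.ndarray:
    """Opening-by-ball background via explicit per-pixel min/max loops.

    The image is treated as +inf outside its domain and ball centers may sit
    anywhere within one radius of the image.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    r = int(radius)
    ys, xs = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = ys**2 + xs**2
    inside = d2 <= r * r
    s = np.sqrt(np.maximum(r * r - d2, 0.0))

    pad = np.pad(img, 2 * r, constant_values=np.inf)
    hc, wc = h + 2 * r, w + 2 * r  # ball-center grid
    ero = np.full((hc, wc), np.inf)
    for cy in range(hc):
        for cx in range(wc):
            win = pad[cy : cy + 2 * r + 1, cx : cx + 2 * r + 1]
            ero[cy, cx] = np.min((win - s)[inside])
    bg = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            win = ero[y : y + 2 * r + 1, x : x + 2 * r + 1]
            bg[y, x] = np.max((win + s)[inside])
    return bg


def coordinate_set_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice via explicit coordinate-set intersection."""
    sa = {tuple(c) for c in np.argwhere(a)}
    sb = {tuple(c) for c in np.argwhere(b)}
    if not sa and not sb:
        return 0.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def closed_form_ols(x, y) -> tuple[float, float]:
    """Slope and intercept of least squares from the normal equations."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return float(slope), float(intercept)
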