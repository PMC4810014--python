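"""Least-squares gradient estimation and border-enhancing segmentation.

The colour score defines a scalar field ``s`` over the image grid (x = column
index increasing rightward, y = row index increasing downward, pixel centres
at integer coordinates).  Its gradient is estimated per pixel by fitting the
local linearisation ``s(r) = grad . (r - rbar) + s(rbar)`` over a square
window by least squares: with displacements ``dr_i`` measured from the
window's mean position, the Gram matrix ``G = sum dr_i (x) dr_i`` and the
measurement vector ``m = sum s(r_i) dr_i`` give ``grad = G^-1 m``.

Smooth borders of spores produce neighbourhoods of large parallel gradients;
averaging the gradient at ``r`` with the gradients at ``r +/- p`` — where
``p = a R n`` steps the offset ``a`` (the learning variable P2) sideways
along the border (R = 90 degree rotation of the gradient direction n) —
enhances such borders and suppresses isolated noise.  Finally, the
extreme-pixel rule keeps pixels whose averaged-gradient magnitude is above
the threshold P3 *and* which have few strictly-greater neighbours in a
square neighbourhood, excluding uniformly sloping regions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError

#: Determinant tolerance below which the local Gram system is rank deficient.
_RANK_TOL = 1e-9


def _window_sums(arr: np.ndarray, size: int) -> np.ndarray:
    """Sum of ``arr`` over the in-bounds size x size window at each pixel."""
    kernel = np.ones((size, size))
    return ndimage.correlate(arr, kernel, mode="constant", cval=0.0)


def estimate_gradient(
    field: np.ndarray, window_radius: int = 2, return_flags: bool = False
):
    """Least-squares gradient of a scalar field over square local windows.

    Parameters
    ----------
    field : (H, W) array
        Scalar field (e.g. the colour score).
    window_radius : int
        Half-width of the fitting window (default 2, a 5x5 window).  Border
        pixels use the truncated in-bounds window; displacements are always
        measured from the in-bounds window's mean position.
    return_flags : bool
        Also return a boolean mask of pixels whose window was rank deficient
        (fewer than 3 non-collinear pixels); their gradient is set to zero.

    Returns
    -------
    grad : (H, W, 2) array of (gx, gy)
    flags : (H, W) bool array, only if ``return_flags``
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2:
        raise ConfigError("scalar field must be 2-D")
    if window_radius < 1:
        raise ConfigError("window_radius must be >= 1")
    if not np.all(np.isfinite(field)):
        raise ConfigError("scalar field must be finite")
    h, w = field.shape
    size = 2 * window_radius + 1
    # coordinates centred on the image to keep moment sums well conditioned
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    xs -= (w - 1) / 2.0
    ys -= (h - 1) / 2.0

    ones = np.ones_like(field)
    n = _window_sums(ones, size)
    sx, sy = _window_sums(xs, size), _window_sums(ys, size)
    sxx, syy = _window_sums(xs * xs, size), _window_sums(ys * ys, size)
    sxy = _window_sums(xs * ys, size)
    ts = _window_sums(field, size)
    tsx, tsy = _window_sums(field * xs, size), _window_sums(field * ys, size)

    # centred second moments of window positions and score-position products
    cxx = sxx - sx * sx / n
    cyy = syy - sy * sy / n
    cxy = sxy - sx * sy / n
    bx = tsx - sx * ts / n
    by = tsy - sy * ts / n

    det = cxx * cyy - cxy * cxy
    bad = det <= _RANK_TOL
    det_safe = np.where(bad, 1.0, det)
    gx = (cyy * bx - cxy * by) / det_safe
    gy = (cxx * by - cxy * bx) / det_safe
    gx[bad] = 0.0
    gy[bad] = 0.0
    grad = np.stack([gx, gy], axis=-1)
    if return_flags:
        return grad, bad
    return grad


def directional_average(grad: np.ndarray, offset_a: float = 3.0) -> np.ndarray:
    """Average each gradient with the gradients one offset to either side.

    At a pixel with gradient ``g`` the unit direction is ``n = g/|g|`` and the
    sideways offset ``p = a R n`` with R the 90 degree counter-clockwise
    rotation (x right, y down).  The output is the mean of the gradients at
    ``r``, ``r + p`` and ``r - p``; off-grid offsets round to the nearest
    pixel and clamp to the image.  Pixels with zero gradient keep their input
    value (direction undefined).

    ``offset_a`` is the learning variable P2, in pixels.
    """
    if offset_a <= 0:
        raise ConfigError("offset_a (P2) must be positive")
    grad = np.asarray(grad, dtype=float)
    h, w = grad.shape[:2]
    mag = np.hypot(grad[..., 0], grad[..., 1])
    nz = mag > 0
    nx = np.where(nz, grad[..., 0] / np.where(nz, mag, 1.0), 0.0)
    ny = np.where(nz, grad[..., 1] / np.where(nz, mag, 1.0), 0.0)
    # +90 deg counter-clockwise on screen (y down): (x, y) -> (y, -x)
    px = offset_a * ny
    py = -offset_a * nx

    ys, xs = np.mgrid[0:h, 0:w]
    out = grad.copy()
    acc = grad.copy()
    for sign in (1.0, -1.0):
        ix = np.clip(np.rint(xs + sign * px).astype(int), 0, w - 1)
        iy = np.clip(np.rint(ys + sign * py).astype(int), 0, h - 1)
        acc += grad[iy, ix]
    out[nz] = acc[nz] / 3.0
    return out


def gradient_magnitude(grad: np.ndarray) -> np.ndarray:
    """Euclidean magnitude of a 2-vector field."""
    grad = np.asarray(grad, dtype=float)
    return np.hypot(grad[..., 0], grad[..., 1])


def extreme_pixel_mask(
    mag: np.ndarray,
    p3: float,
    neighbourhood_side: int = 7,
    top_fraction: float = 0.25,
) -> np.ndarray:
    """Pixels above P3 with few strictly-greater neighbours.

    A pixel passes iff ``mag > P3`` and strictly fewer than
    ``top_fraction * (N - 1)`` of its in-bounds neighbours have strictly
    greater magnitude, where N is the in-bounds neighbourhood size (the
    pixel itself excluded from the count).  Plateaus pass (strict
    inequalities); the rule is rank-based, hence invariant under monotone
    transforms of the magnitudes that preserve the P3 threshold set.
    """
    mag = np.asarray(mag, dtype=float)
    if neighbourhood_side < 1 or neighbourhood_side % 2 == 0:
        raise ConfigError("neighbourhood_side must be odd and positive")
    if not 0.0 < top_fraction < 1.0:
        raise ConfigError("top_fraction must be in (0, 1)")
    r = neighbourhood_side // 2
    h, w = mag.shape
    padded = np.pad(mag, r, mode="constant", constant_values=-np.inf)
    inb = np.pad(np.ones_like(mag), r, mode="constant", constant_values=0.0)

    greater = np.zeros(mag.shape, dtype=np.int32)
    count = np.zeros(mag.shape, dtype=np.int32)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy == 0 and dx == 0:
                continue
            sl = (slice(r + dy, r + dy + h), slice(r + dx, r + dx + w))
            greater += padded[sl] > mag
            count += inb[sl].astype(np.int32)
    n_minus_1 = count  # N includes the centre pixel; neighbours = N - 1
    return (mag > p3) & (greater < top_fraction * n_minus_1)
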