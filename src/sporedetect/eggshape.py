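"""Three-parameter egg shapes: generation, curve distances, and perimeter fitting.

Morphologically opened projections of *P. neoaphidis* conidia resemble eggs or
ovals.  The egg family used here is the image of the unit disc D under two
simple maps: a taper ``F_c:(x,y) -> (x, (c*x + 1)*y)`` followed by the scaling
``G_{a,b}:(x,y) -> (a*x, b*y)``, giving the boundary curve

    (a*cos t,  b*(c*cos t + 1)*sin t),   t in [0, 2*pi).

``a`` and ``b`` scale the long and short semi-axes and the taper ``c``
(|c| < 1, so c*x + 1 > 0 over the disc and the map is injective) narrows one
end.  The family has the symmetry (theta, c) <-> (theta + pi, -c); fits are
canonicalised to c >= 0.

Goodness of fit between an egg curve and a blob perimeter combines the
Hausdorff distance

    d_H(X, Y) = max( sup_x inf_y d(x,y),  sup_y inf_x d(x,y) )

with the squared-distance curve integral

    d_L2 = integral over the egg curve of  d(r, dB)^2  ds,

d(r, dB) being the distance from r to the blob perimeter.  The combined
objective is ``w * d_H + (1 - w) * sqrt(d_L2 / perimeter)`` so both terms are
lengths in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .blobs import AxisInfo, Blob, principal_axis
from .exceptions import ConfigError, DegenerateBlobError

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class EggShape:
    """Egg parameters: semi-axis scales a, b > 0 and taper |c| < 1."""

    a: float
    b: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ConfigError("egg scales a, b must be positive")
        if abs(self.c) >= 1:
            raise ConfigError("taper must satisfy |c| < 1 (injective map)")


@dataclass(frozen=True)
class Pose:
    """Placement of an egg in image coordinates: centre (pixels) and rotation.

    ``theta`` is stored in [0, 2*pi); when the taper vanishes the curve has a
    180-degree ambiguity and theta collapses to [0, pi).
    """

    center: np.ndarray
    theta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(2))
        object.__setattr__(self, "theta", float(self.theta) % TWO_PI)


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the egg fit."""

    weight: float = 0.5          # Hausdorff weight w in the combined score
    n_points_fit: int = 256      # boundary samples during optimisation
    n_points_final: int = 1024   # boundary samples for reported distances
    max_evals: int = 500         # function-evaluation cap per start
    c_starts: tuple[float, ...] = (0.0, 0.3, -0.3)
    max_taper: float = 0.95      # search bound on |c|


@dataclass(frozen=True)
class EggFit:
    """Result of fitting an egg to a blob perimeter."""

    shape: EggShape
    pose: Pose
    d_hausdorff: float
    d_l2: float
    score: float
    converged: bool
    n_evals: int


def egg_boundary(shape: EggShape, pose: Pose | None = None, n_points: int = 256) -> np.ndarray:
    """Sample the egg curve as an (n, 2) polygon (closed ring, first point not repeated).

    Vertices are ``(a cos t, b (c cos t + 1) sin t)`` rotated by ``pose.theta``
    and translated to ``pose.center``; counter-clockwise (positive shoelace
    area) in (x, y) coordinates.
    """
    if n_points < 16:
        raise ConfigError("egg boundary needs at least 16 points")
    t = np.linspace(0.0, TWO_PI, n_points, endpoint=False)
    x = shape.a * np.cos(t)
    y = shape.b * (shape.c * np.cos(t) + 1.0) * np.sin(t)
    pts = np.column_stack([x, y])
    if pose is not None:
        ct, st = math.cos(pose.theta), math.sin(pose.theta)
        rot = np.array([[ct, -st], [st, ct]])
        pts = pts @ rot.T + pose.center
    return pts


def egg_normals(shape: EggShape, pose: Pose | None = None, n_points: int = 256) -> np.ndarray:
    """Outward unit normals at the vertices of :func:`egg_boundary`."""
    t = np.linspace(0.0, TWO_PI, n_points, endpoint=False)
    # tangent from the analytic derivative of the boundary parameterisation
    dx = -shape.a * np.sin(t)
    dy = shape.b * (shape.c * (np.cos(t) ** 2 - np.sin(t) ** 2) + np.cos(t))
    normals = np.column_stack([dy, -dx])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # orient outward relative to the local-frame curve centroid
    local = egg_boundary(shape, None, n_points)
    centre = local.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, local - centre) < 0
    normals[flip] = -normals[flip]
    if pose is not None:
        ct, st = math.cos(pose.theta), math.sin(pose.theta)
        rot = np.array([[ct, -st], [st, ct]])
        normals = normals @ rot.T
    return normals


def hausdorff_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two vertex-sampled curves."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("Hausdorff distance needs non-empty point sets")
    d = cdist(x, y)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def _point_to_segments(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest segment of a closed polygon."""
    a = poly
    ab = np.roll(poly, -1, axis=0) - a  # (K, 2)
    ab2 = np.maximum(ab[:, 0] ** 2 + ab[:, 1] ** 2, 1e-300)
    apx = points[:, 0][:, None] - a[:, 0][None, :]  # (M, K)
    apy = points[:, 1][:, None] - a[:, 1][None, :]
    t = np.clip((apx * ab[:, 0] + apy * ab[:, 1]) / ab2, 0.0, 1.0)
    dx = apx - t * ab[:, 0]
    dy = apy - t * ab[:, 1]
    d2 = dx * dx + dy * dy
    return np.sqrt(d2.min(axis=1))


def l2_curve_distance(egg: np.ndarray, blob_boundary: np.ndarray) -> float:
    """Discretised curve integral of squared distance to the blob perimeter.

    Sums, over the egg polygon's segments, the squared distance from the
    segment midpoint to the nearest point on any blob-boundary segment,
    weighted by segment length.  Units: pixels cubed.
    """
    egg = np.asarray(egg, dtype=float)
    blob_boundary = np.asarray(blob_boundary, dtype=float)
    if len(egg) < 2 or len(blob_boundary) < 2:
        raise ConfigError("curve distance needs at least 2 points per curve")
    nxt = np.roll(egg, -1, axis=0)
    mids = 0.5 * (egg + nxt)
    seglen = np.linalg.norm(nxt - egg, axis=1)
    d = _point_to_segments(mids, blob_boundary)
    return float(np.sum(d * d * seglen))


def combined_score(egg_poly: np.ndarray, blob_poly: np.ndarray, weight: float = 0.5) -> float:
    """w * d_H + (1 - w) * RMS curve distance (both in pixels)."""
    d_h = hausdorff_distance(egg_poly, blob_poly)
    perimeter = float(np.linalg.norm(np.roll(egg_poly, -1, axis=0) - egg_poly, axis=1).sum())
    rms = math.sqrt(l2_curve_distance(egg_poly, blob_poly) / perimeter)
    return weight * d_h + (1.0 - weight) * rms


def canonicalise(shape: EggShape, pose: Pose) -> tuple[EggShape, Pose]:
    """Resolve the (theta, c) <-> (theta + pi, -c) ambiguity: c >= 0."""
    a, b, c = shape.a, shape.b, shape.c
    theta = pose.theta
    if c < 0:
        c = -c
        theta = theta + math.pi
    theta = theta % TWO_PI
    if abs(c) < 1e-12:
        theta = theta % math.pi
    return EggShape(a, b, c), Pose(pose.center, theta)


def fit_egg(blob: Blob, config: FitConfig | None = None, axis_info: AxisInfo | None = None) -> EggFit:
    """Fit egg shape and pose to a blob's perimeter.

    Initialised from the blob centroid, principal-axis angle and half
    extents; multi-started over taper seeds (the (theta+pi, -c) symmetry
    makes the two axis orientations redundant, so only distinct taper seeds
    are run).  Minimisation is derivative-free (Nelder-Mead) on the combined
    Hausdorff / RMS-curve-distance score with a fixed evaluation cap per
    start.
    """
    config = config or FitConfig()
    if len(blob) < 2:
        raise DegenerateBlobError("cannot fit an egg to fewer than 2 pixels")
    boundary = blob.boundary
    info = axis_info or principal_axis(blob, pixel_size_um=1.0)
    # extents in pixels regardless of the AxisInfo's physical calibration
    px_info = info if axis_info is None else principal_axis(blob, pixel_size_um=1.0)
    a0 = max(px_info.length_um / 2.0, 1.0)
    b0 = max(px_info.width_um / 2.0, 1.0)
    theta0 = math.atan2(px_info.axis[1], px_info.axis[0])
    cx0, cy0 = blob.centroid

    w = config.weight
    n_fit = config.n_points_fit
    cmax = config.max_taper

    def objective(params: np.ndarray) -> float:
        a, b, c, cx, cy, theta = params
        if a <= 0.5 or b <= 0.5 or abs(c) >= cmax:
            return 1e6 + abs(a) + abs(b) + abs(c)
        egg = egg_boundary(EggShape(a, b, float(c)), Pose((cx, cy), theta), n_fit)
        return combined_score(egg, boundary, w)

    best = None
    total_evals = 0
    converged = False
    for c_start in config.c_starts:
        x0 = np.array([a0, b0, c_start, cx0, cy0, theta0])
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": config.max_evals,
                "xatol": 1e-2,
                "fatol": 1e-3,
                "adaptive": True,
            },
        )
        total_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    a, b, c, cx, cy, theta = best.x
    c = float(np.clip(c, -cmax, cmax))
    shape, pose = canonicalise(EggShape(max(a, 1e-6), max(b, 1e-6), c), Pose((cx, cy), theta))
    egg_final = egg_boundary(shape, pose, config.n_points_final)
    d_h = hausdorff_distance(egg_final, boundary)
    d_l2 = l2_curve_distance(egg_final, boundary)
    perimeter = float(np.linalg.norm(np.roll(egg_final, -1, axis=0) - egg_final, axis=1).sum())
    score = w * d_h + (1.0 - w) * math.sqrt(d_l2 / perimeter)
    return EggFit(
        shape=shape,
        pose=pose,
        d_hausdorff=d_h,
        d_l2=d_l2,
        score=score,
        converged=converged,
        n_evals=total_evals,
    )


@dataclass(frozen=True)
class CheckResult:
    """Outcome of a validation check; ``valid`` is False when inconclusive."""

    value: float
    valid: bool = True


#: Chance-level alignment of random gradient directions with any fixed
#: normal: E|cos U| over the circle = 2/pi.
RANDOM_ALIGNMENT = 2.0 / math.pi


def outer_curve(
    fit: EggFit, margin_px: float, n_points: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Curve offset outward from the fitted egg along local normals.

    Returns (points, outward unit normals)."""
    pts = egg_boundary(fit.shape, fit.pose, n_points)
    normals = egg_normals(fit.shape, fit.pose, n_points)
    return pts + margin_px * normals, normals


def gradient_normal_check(
    fit: EggFit,
    grad: np.ndarray,
    outer_margin_um: float = 2.0,
    pixel_size_um: float = 0.5063,
    n_samples: int = 256,
) -> CheckResult:
    """Mean |cos| alignment of the averaged gradient with the egg's outward normals.

    Sampled on the outer curve (the fitted egg offset outward by
    ``outer_margin_um``).  A real spore's smooth border produces gradients
    mainly along these normals (alignment near 1); random texture gives the
    chance level 2/pi.  If more than half the sampled gradients vanish the
    check is inconclusive and returns the chance level flagged invalid.
    """
    margin_px = outer_margin_um / pixel_size_um
    pts, normals = outer_curve(fit, margin_px, n_samples)
    h, w = grad.shape[:2]
    ix = np.clip(np.rint(pts[:, 0]).astype(int), 0, w - 1)
    iy = np.clip(np.rint(pts[:, 1]).astype(int), 0, h - 1)
    g = grad[iy, ix]
    mag = np.linalg.norm(g, axis=1)
    ok = mag > 0
    if ok.sum() < n_samples / 2:
        return CheckResult(RANDOM_ALIGNMENT, valid=False)
    cosang = np.einsum("ij,ij->i", g[ok], normals[ok]) / mag[ok]
    return CheckResult(float(np.mean(np.abs(cosang))))


def background_correlation_check(
    image: np.ndarray,
    fit: EggFit,
    outer_margin_um: float = 2.0,
    pixel_size_um: float = 0.5063,
    n_samples: int = 256,
    inner_scale: float = 0.7,
) -> CheckResult:
    """Pearson correlation of inner vs outer luminance at matched angles.

    Inner samples lie on the fitted egg scaled by ``inner_scale``; outer
    samples on the outer curve.  The colour of a real spore does not
    correlate with its background, whereas background texture continuing
    through the blob produces a strong correlation (candidate rejected above
    the configured threshold).  Constant samples make the correlation
    undefined: flagged neutral 0.
    """
    margin_px = outer_margin_um / pixel_size_um
    inner_shape = EggShape(fit.shape.a * inner_scale, fit.shape.b * inner_scale, fit.shape.c)
    inner_pts = egg_boundary(inner_shape, fit.pose, n_samples)
    outer_pts, _ = outer_curve(fit, margin_px, n_samples)
    h, w = image.shape[:2]

    def lum(pts: np.ndarray) -> np.ndarray:
        ix = np.clip(np.rint(pts[:, 0]).astype(int), 0, w - 1)
        iy = np.clip(np.rint(pts[:, 1]).astype(int), 0, h - 1)
        return image[iy, ix].astype(float).mean(axis=1)

    inner = lum(inner_pts)
    outer = lum(outer_pts)
    if inner.std() < 1e-12 or outer.std() < 1e-12:
        return CheckResult(0.0, valid=False)
    return CheckResult(float(np.corrcoef(inner, outer)[0, 1]))
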