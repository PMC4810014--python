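"""Synthetic slide scenes with ground truth.

Generates RGB images that emulate the structure of stained spore-trap slide
photographs: a bright background, obovoid spores 15-40 um long and 9-16 um
wide whose interior RGB values lie on a strongly correlated colour line
(blue component spanning roughly 100-250, rising with red and green), and
small saturated "blue dot" dust distractors off that line.  Scenes are
rendered at the microscope's pixel scale (0.5063 um/px by default) with
anti-aliased borders (4x supersampled coverage), Gaussian blur and additive
pixel noise.  Rendering is deterministic for a given seed.

The generator emulates colour statistics and blob geometry, not optics: there
is no per-spore defocus (a single global blur stands in for the slide's one
focal plane) and no staining-chemistry colour physics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .eggshape import EggShape, Pose
from .exceptions import ConfigError, PlacementError

DEFAULT_PIXEL_SIZE_UM = 0.5063

_SUPERSAMPLE = 4  # anti-aliasing subdivisions per pixel edge


@dataclass(frozen=True)
class SceneSpec:
    """Description of one synthetic slide scene.

    Colour defaults emulate the observed spore colour line: interior pixel
    values run from a dark end near (60, 75, 100) to a bright end near
    (210, 220, 250), so blue spans about 100-250 and the channels are
    strongly correlated.  Dust is saturated blue off that line.
    """

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_spores: int = 5
    spore_length_range_um: tuple[float, float] = (15.0, 40.0)
    spore_width_range_um: tuple[float, float] = (9.0, 16.0)
    taper_range: tuple[float, float] = (0.1, 0.5)
    colour_line_start: tuple[float, float, float] = (60.0, 75.0, 100.0)
    colour_line_end: tuple[float, float, float] = (210.0, 220.0, 250.0)
    colour_jitter: float = 4.0     # isotropic per-pixel RGB jitter (sigma)
    colour_t_sigma: float = 0.12   # per-pixel spread along the line
    n_dust: int = 20
    dust_colour: tuple[float, float, float] = (45.0, 60.0, 190.0)
    dust_colour_jitter: float = 10.0
    dust_diameter_range_um: tuple[float, float] = (3.0, 8.0)
    blur_sigma_px: float = 1.0
    noise_sigma: float = 2.5
    background_rgb: tuple[float, float, float] = (231.0, 233.0, 240.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("scene dimensions and pixel size must be positive")
        for lo, hi in (
            self.spore_length_range_um,
            self.spore_width_range_um,
            self.dust_diameter_range_um,
        ):
            if not 0 < lo <= hi:
                raise ConfigError("size ranges must be positive with min <= max")
        lo, hi = self.taper_range
        if not -1 < lo <= hi < 1:
            raise ConfigError("taper range must lie within (-1, 1)")


@dataclass(frozen=True)
class SporeRecord:
    """Ground truth for one rendered spore."""

    center: tuple[float, float]
    theta: float
    a_px: float
    b_px: float
    c: float
    length_um: float
    width_um: float

    @property
    def shape(self) -> EggShape:
        return EggShape(self.a_px, self.b_px, self.c)

    @property
    def pose(self) -> Pose:
        return Pose(self.center, self.theta)


@dataclass(frozen=True)
class DustRecord:
    center: tuple[float, float]
    radius_px: float


@dataclass(frozen=True)
class GroundTruth:
    spores: list[SporeRecord] = field(default_factory=list)
    dust: list[DustRecord] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spores": [asdict(s) for s in self.spores],
            "dust": [asdict(d) for d in self.dust],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            spores=[
                SporeRecord(**{**s, "center": tuple(s["center"])})
                for s in payload["spores"]
            ],
            dust=[DustRecord(center=tuple(d["center"]), radius_px=d["radius_px"]) for d in payload["dust"]],
        )


def _width_factor(c: float) -> float:
    """max over t of (c cos t + 1) sin t: the egg's half-width in units of b."""
    t = np.linspace(0.0, math.pi, 2048)
    return float(np.max((c * np.cos(t) + 1.0) * np.sin(t)))


def _inside_fraction(
    shape: EggShape, pose: Pose, x0: int, y0: int, nx: int, ny: int, supersample: int
) -> np.ndarray:
    """Coverage fraction of the egg over an (ny, nx) pixel box at (x0, y0)."""
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    xs = x0 + np.arange(nx)[:, None] + off[None, :]  # (nx, s)
    ys = y0 + np.arange(ny)[:, None] + off[None, :]
    xg = xs.reshape(1, -1) * np.ones((ny * s, 1))
    yg = ys.reshape(-1, 1) * np.ones((1, nx * s))
    # invert pose, then G, then F to test membership in the unit disc
    ct, st = math.cos(pose.theta), math.sin(pose.theta)
    dx = xg - pose.center[0]
    dy = yg - pose.center[1]
    lx = ct * dx + st * dy
    ly = -st * dx + ct * dy
    u = lx / shape.a
    g = shape.c * u + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(g > 0, ly / (shape.b * g), np.inf)
    inside = (u * u + v * v) <= 1.0
    return inside.reshape(ny, s, nx, s).mean(axis=(1, 3))


def render_blob_mask(
    shape: EggShape, pose: Pose, grid_shape: tuple[int, int]
) -> np.ndarray:
    """Binary mask of pixels whose centres lie inside the posed egg.

    Membership is exact: a pixel centre p is inside iff its pre-image under
    the scaling G then the taper F lies in the unit disc.  Warns when the
    shape extends beyond the grid (mask truncated).
    """
    h, w = grid_shape
    frac = _inside_fraction(shape, pose, 0, 0, w, h, supersample=1)
    mask = frac > 0.5
    # quick extent check in the egg's local frame
    reach = max(shape.a, shape.b * (1.0 + abs(shape.c)))
    cx, cy = pose.center
    if cx - reach < -0.5 or cy - reach < -0.5 or cx + reach > w - 0.5 or cy + reach > h - 0.5:
        warnings.warn("egg shape extends outside the grid; mask truncated", stacklevel=2)
    return mask


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a slide-like scene; returns (uint8 RGB image, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    px = spec.pixel_size_um

    spores: list[SporeRecord] = []
    max_retries = 200 * max(spec.n_spores, 1)
    retries = 0
    while len(spores) < spec.n_spores:
        if retries > max_retries:
            raise PlacementError(
                f"could not place {spec.n_spores} spores without overlap "
                f"in a {w}x{h} px scene"
            )
        length = rng.uniform(*spec.spore_length_range_um)
        width = rng.uniform(*spec.spore_width_range_um)
        if width >= 0.95 * length:
            retries += 1
            continue
        c = rng.uniform(*spec.taper_range)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        a_px = (length / 2.0) / px
        b_px = (width / 2.0) / px / _width_factor(c)
        reach = max(a_px, b_px * (1.0 + abs(c)))
        margin = reach + 6.0
        if 2 * margin >= min(w, h):
            raise PlacementError("scene too small for the configured spore sizes")
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        ok = all(
            math.hypot(cx - s.center[0], cy - s.center[1])
            > reach + max(s.a_px, s.b_px * (1 + abs(s.c))) + 6.0
            for s in spores
        )
        if not ok:
            retries += 1
            continue
        spores.append(
            SporeRecord(
                center=(cx, cy), theta=theta, a_px=a_px, b_px=b_px, c=c,
                length_um=length, width_um=width,
            )
        )

    dust: list[DustRecord] = []
    for _ in range(spec.n_dust):
        r_px = rng.uniform(*spec.dust_diameter_range_um) / 2.0 / px
        for _attempt in range(200):
            cx = rng.uniform(r_px + 2, w - r_px - 2)
            cy = rng.uniform(r_px + 2, h - r_px - 2)
            clear = all(
                math.hypot(cx - s.center[0], cy - s.center[1])
                > max(s.a_px, s.b_px * (1 + abs(s.c))) + r_px + 4.0
                for s in spores
            )
            if clear:
                dust.append(DustRecord(center=(cx, cy), radius_px=r_px))
                break
        else:
            raise PlacementError("could not place dust clear of spores")

    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = np.asarray(spec.background_rgb, dtype=float)

    start = np.asarray(spec.colour_line_start, dtype=float)
    end = np.asarray(spec.colour_line_end, dtype=float)
    for s in spores:
        shape, pose = s.shape, s.pose
        reach = max(s.a_px, s.b_px * (1 + abs(s.c))) + 3.0
        x0 = max(int(math.floor(s.center[0] - reach)), 0)
        y0 = max(int(math.floor(s.center[1] - reach)), 0)
        x1 = min(int(math.ceil(s.center[0] + reach)) + 1, w)
        y1 = min(int(math.ceil(s.center[1] + reach)) + 1, h)
        frac = _inside_fraction(shape, pose, x0, y0, x1 - x0, y1 - y0, _SUPERSAMPLE)
        t_spore = rng.uniform(0.2, 0.8)
        t_pix = np.clip(
            t_spore + rng.normal(0.0, spec.colour_t_sigma, frac.shape), 0.0, 1.0
        )
        colour = start + t_pix[..., None] * (end - start)
        colour += rng.normal(0.0, spec.colour_jitter, colour.shape)
        alpha = frac[..., None]
        canvas[y0:y1, x0:x1] = (1.0 - alpha) * canvas[y0:y1, x0:x1] + alpha * colour

    dust_rgb = np.asarray(spec.dust_colour, dtype=float)
    for d in dust:
        r = d.radius_px
        x0 = max(int(math.floor(d.center[0] - r - 2)), 0)
        y0 = max(int(math.floor(d.center[1] - r - 2)), 0)
        x1 = min(int(math.ceil(d.center[0] + r + 2)) + 1, w)
        y1 = min(int(math.ceil(d.center[1] + r + 2)) + 1, h)
        circle = EggShape(r, r, 0.0)
        frac = _inside_fraction(circle, Pose(d.center), x0, y0, x1 - x0, y1 - y0, _SUPERSAMPLE)
        colour = dust_rgb + rng.normal(0.0, spec.dust_colour_jitter, (y1 - y0, x1 - x0, 3))
        alpha = frac[..., None]
        canvas[y0:y1, x0:x1] = (1.0 - alpha) * canvas[y0:y1, x0:x1] + alpha * colour

    if spec.blur_sigma_px > 0:
        for ch in range(3):
            canvas[..., ch] = ndimage.gaussian_filter(canvas[..., ch], spec.blur_sigma_px)
    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return image, GroundTruth(spores=spores, dust=dust)


def harvest_training_pixels(
    image: np.ndarray, truth: GroundTruth, n: int, seed: int = 0
) -> np.ndarray:
    """Sample RGB pixels uniformly from interior spore regions.

    Interiors are the ground-truth egg masks eroded by 1 px to avoid border
    mixing.  If fewer than ``n`` interior pixels exist, all are returned with
    a warning.
    """
    if not truth.spores:
        raise ConfigError("ground truth contains no spores to harvest from")
    h, w = image.shape[:2]
    interior = np.zeros((h, w), dtype=bool)
    for s in truth.spores:
        interior |= render_blob_mask(s.shape, s.pose, (h, w))
    interior = ndimage.binary_erosion(interior, structure=np.ones((3, 3), dtype=bool))
    ys, xs = np.nonzero(interior)
    if len(ys) <= n:
        if len(ys) < n:
            warnings.warn(
                f"only {len(ys)} interior pixels available (requested {n})",
                stacklevel=2,
            )
        return image[ys, xs].astype(float)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ys), size=n, replace=False)
    return image[ys[idx], xs[idx]].astype(float)
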