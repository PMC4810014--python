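"""Blob extraction and shape statistics for candidate spores.

The segmentation mask is regularised by morphological closing with a disc of
fixed physical radius (default 3 um), split into connected components, and
each component is replaced by its convex hull and then opened with a smaller
disc (default 2 um).  Surviving blobs are measured: the principal axis is the
direction ``n`` maximising ``S = sum (n . r_i)**2`` over centred pixel
positions (equivalently minimising the summed squared cross products
``|n x r_i|**2``), and length/width are the pixel extents along the axis and
its normal, converted to micrometres.  Primary conidia of *P. neoaphidis*
measure 15-40 um by 9-16 um; secondary conidia 16-25 um by 7-15 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import convex_hull_image

from .exceptions import ConfigError, DegenerateBlobError

DEFAULT_PIXEL_SIZE_UM = 0.5063

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)
_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class SizeBounds:
    """Inclusive physical bounds on blob length and width, in micrometres."""

    length_min_um: float
    length_max_um: float
    width_min_um: float
    width_max_um: float

    def __post_init__(self) -> None:
        if not (0 < self.length_min_um < self.length_max_um):
            raise ConfigError("length bounds must satisfy 0 < min < max")
        if not (0 < self.width_min_um < self.width_max_um):
            raise ConfigError("width bounds must satisfy 0 < min < max")


#: Primary conidia: clavate/obovoid, length 15-40 um, width 9-16 um.
PRIMARY_CONIDIA = SizeBounds(15.0, 40.0, 9.0, 16.0)
#: Secondary conidia: length 16-25 um, width 7-15 um.
SECONDARY_CONIDIA = SizeBounds(16.0, 25.0, 7.0, 15.0)


@dataclass(frozen=True)
class AxisInfo:
    """Principal axis and physical extents of a blob."""

    axis: np.ndarray  # unit 2-vector (x, y)
    length_um: float
    width_um: float
    isotropic: bool = False


@dataclass(frozen=True)
class Blob:
    """Connected pixel region on an image grid.

    ``pixels`` holds integer (x, y) coordinates, x = column.  The outer
    boundary is traced on demand as a closed sub-pixel polygon with positive
    shoelace area (counter-clockwise in (x, y) coordinate terms).
    """

    pixels: np.ndarray
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=int).reshape(-1, 2))

    def __len__(self) -> int:
        return self.pixels.shape[0]

    @cached_property
    def centroid(self) -> np.ndarray:
        return self.pixels.mean(axis=0)

    @cached_property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.pixels[:, 1], self.pixels[:, 0]] = True
        return m

    @cached_property
    def boundary(self) -> np.ndarray:
        """Outer contour as an (n, 2) polygon of (x, y) vertices (open ring)."""
        padded = np.pad(self.mask, 1)
        contours = measure.find_contours(padded.astype(float), 0.5)
        if not contours:  # pragma: no cover - non-empty blobs always contour
            raise DegenerateBlobError("blob has no traceable boundary")
        contour = max(contours, key=len)
        poly = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
        if np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if _shoelace(poly) < 0:
            poly = poly[::-1]
        return poly


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def disc_footprint(radius_um: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> np.ndarray:
    """Discrete Euclidean disc {(dx,dy): dx^2+dy^2 <= r^2}, r = round(um/px)."""
    if radius_um <= 0 or pixel_size_um <= 0:
        raise ConfigError("radius and pixel size must be positive")
    r = int(round(radius_um / pixel_size_um))
    if r == 0:
        raise ConfigError(
            f"structuring radius {radius_um} um rounds to 0 px at {pixel_size_um} um/px"
        )
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dx * dx + dy * dy) <= r * r


def close_mask(
    mask: np.ndarray,
    radius_um: float = 3.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> np.ndarray:
    """Morphological closing with a disc of fixed physical radius (extensive)."""
    fp = disc_footprint(radius_um, pixel_size_um)
    r = fp.shape[0] // 2
    padded = np.pad(np.asarray(mask, dtype=bool), r)
    closed = ndimage.binary_closing(padded, structure=fp)
    return closed[r:-r, r:-r]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return _STRUCTURE_8
    if connectivity == 4:
        return _STRUCTURE_4
    raise ConfigError("connectivity must be 4 or 8")


def connected_components(mask: np.ndarray, connectivity: int = 8) -> list[Blob]:
    """Split a mask into blobs, ordered by (min row, min column)."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    blobs = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        ys, xs = np.nonzero(labels[sl] == lab)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        blobs.append(
            (int(ys.min()), int(xs.min()), Blob(np.column_stack([xs, ys]), mask.shape))
        )
    blobs.sort(key=lambda t: (t[0], t[1]))
    return [b for _, _, b in blobs]


def convex_hull_blob(blob: Blob) -> Blob:
    """Replace a blob's pixels by all pixels whose centres lie in their hull."""
    if len(blob) == 0:
        raise DegenerateBlobError("cannot take the hull of an empty blob")
    xs, ys = blob.pixels[:, 0], blob.pixels[:, 1]
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    local = np.zeros((y1 - y0 + 1, x1 - x0 + 1), dtype=bool)
    local[ys - y0, xs - x0] = True
    if x0 == x1 or y0 == y1:
        # axis-aligned line: the hull segment covers every centre between ends
        local[:] = True
    elif local.sum() > 2:
        hulled = convex_hull_image(local, offset_coordinates=False)
        if hulled.any():  # qhull degenerates on collinear sets; keep input then
            local = hulled
    ly, lx = np.nonzero(local)
    return Blob(np.column_stack([lx + x0, ly + y0]), blob.grid_shape)


def open_blob(
    blob: Blob,
    radius_um: float = 2.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[Blob]:
    """Morphological opening of one blob (anti-extensive).

    Opening may erase a thin blob entirely (empty list) or split it; the
    resulting components are returned largest first.
    """
    fp = disc_footprint(radius_um, pixel_size_um)
    r = fp.shape[0] // 2
    if len(blob) == 0:
        return []
    xs, ys = blob.pixels[:, 0], blob.pixels[:, 1]
    x0, y0 = xs.min(), ys.min()
    local = np.zeros((ys.max() - y0 + 1 + 2 * r, xs.max() - x0 + 1 + 2 * r), dtype=bool)
    local[ys - y0 + r, xs - x0 + r] = True
    opened = ndimage.binary_opening(local, structure=fp)
    labels, n = ndimage.label(opened, structure=_STRUCTURE_8)
    pieces = []
    for lab in range(1, n + 1):
        ly, lx = np.nonzero(labels == lab)
        pieces.append(Blob(np.column_stack([lx + x0 - r, ly + y0 - r]), blob.grid_shape))
    pieces.sort(key=len, reverse=True)
    return pieces


def erode_blob(
    blob: Blob,
    radius_um: float,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[Blob]:
    """Morphological erosion of one blob by a disc of fixed physical radius.

    Used by the pipeline to compensate the outward displacement of the
    gradient-crest segmentation ring relative to the true region border.
    Components are returned largest first; a blob thinner than the disc
    vanishes (empty list).
    """
    fp = disc_footprint(radius_um, pixel_size_um)
    r = fp.shape[0] // 2
    if len(blob) == 0:
        return []
    xs, ys = blob.pixels[:, 0], blob.pixels[:, 1]
    x0, y0 = xs.min(), ys.min()
    local = np.zeros((ys.max() - y0 + 1 + 2 * r, xs.max() - x0 + 1 + 2 * r), dtype=bool)
    local[ys - y0 + r, xs - x0 + r] = True
    eroded = ndimage.binary_erosion(local, structure=fp)
    labels, n = ndimage.label(eroded, structure=_STRUCTURE_8)
    pieces = []
    for lab in range(1, n + 1):
        ly, lx = np.nonzero(labels == lab)
        pieces.append(Blob(np.column_stack([lx + x0 - r, ly + y0 - r]), blob.grid_shape))
    pieces.sort(key=len, reverse=True)
    return pieces


def principal_axis(
    blob: Blob, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> AxisInfo:
    """Dominant axis of a blob's pixel scatter, with physical extents.

    The axis maximises the summed squared projections of centred pixel
    positions; extents are (max - min) of the projections on the axis and its
    normal plus one pixel (pixel area, not centre span), times the pixel size.
    A blob with equal scatter eigenvalues is flagged isotropic and gets the
    default axis (1, 0).
    """
    if len(blob) < 2:
        raise DegenerateBlobError("principal axis needs at least 2 pixels")
    pts = blob.pixels.astype(float) - blob.centroid
    scatter = pts.T @ pts
    lam, vec = np.linalg.eigh(scatter)  # ascending
    isotropic = (lam[1] - lam[0]) <= 1e-9 * max(lam[1], 1.0)
    if isotropic:
        axis = np.array([1.0, 0.0])
    else:
        axis = vec[:, 1]
        nz = np.nonzero(np.abs(axis) > 1e-12)[0][0]
        if axis[nz] < 0:
            axis = -axis
    normal = np.array([-axis[1], axis[0]])
    proj = pts @ axis
    perp = pts @ normal
    length_px = proj.max() - proj.min() + 1.0
    width_px = perp.max() - perp.min() + 1.0
    length_um = length_px * pixel_size_um
    width_um = width_px * pixel_size_um
    # 'length' is always the extent along the variance-maximising axis; for
    # irregular point sets it can be marginally smaller than the normal
    # extent, but for the convex spore-like blobs of this pipeline the
    # orderings agree
    return AxisInfo(axis=axis, length_um=length_um, width_um=width_um, isotropic=isotropic)


def size_filter(info: AxisInfo, bounds: SizeBounds = PRIMARY_CONIDIA) -> bool:
    """True iff extents lie within the conidium bounds (inclusive)."""
    return (
        bounds.length_min_um <= info.length_um <= bounds.length_max_um
        and bounds.width_min_um <= info.width_um <= bounds.width_max_um
    )
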