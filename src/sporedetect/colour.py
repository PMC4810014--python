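"""Spore colour model: PCA of spore RGB samples and per-pixel likelihood scoring.

Pixels sampled from the interior of stained *Pandora neoaphidis* conidia occupy
a nearly one-dimensional, strongly correlated structure in RGB space: the blue
component spans roughly 100-250 and rises and falls together with red and
green.  A principal component analysis of the centred second-moment matrix of
such samples captures that line.  The colour-likelihood score of a pixel ``p``
is the Mahalanobis quadratic form

    s(p) = sum_i  c_i**2 / lambda_i,   c_i = v_i . (p - mean),

where ``lambda_1 >= lambda_2 >= lambda_3 > 0`` are the eigenvalues of the
scatter and ``v_i`` the orthonormal eigenvectors.  Small scores mark pixels
within the spore colour distribution; a pixel is classified spore-coloured
when ``s < P1`` (strict).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateModelError, FormatError, TrainingError

#: Relative floor applied to the smallest eigenvalues so scores stay finite
#: for near-degenerate training sets.
EIGENVALUE_FLOOR = 1e-6

DEFAULT_MIN_SAMPLES = 50

#: Default score threshold P1 (~3 sigma in 3 dimensions); data-product
#: dependent, normally taken from :class:`~sporedetect.pipeline.DetectionConfig`.
DEFAULT_P1 = 9.0


@dataclass(frozen=True)
class SporeColourModel:
    """Eigenstructure of the spore RGB distribution.

    Attributes
    ----------
    mean : (3,) float array
        Sample mean RGB vector.
    eigenvalues : (3,) float array
        Descending, strictly positive (floored at ``EIGENVALUE_FLOOR * lambda1``).
    eigenvectors : (3, 3) float array
        Rows ``v1, v2, v3``, orthonormal.
    n_samples : int
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "eigenvalues", np.asarray(self.eigenvalues, dtype=float))
        object.__setattr__(self, "eigenvectors", np.asarray(self.eigenvectors, dtype=float))
        lam = self.eigenvalues
        if lam.shape != (3,) or np.any(np.diff(lam) > 0) or lam[-1] <= 0:
            raise ValueError("eigenvalues must be sorted descending and strictly positive")
        v = self.eigenvectors
        if v.shape != (3, 3) or not np.allclose(v @ v.T, np.eye(3), atol=1e-9):
            raise ValueError("eigenvectors must form an orthonormal 3x3 matrix")

    @property
    def total_variance(self) -> float:
        """Mean square deviation of the RGB vector: lambda1 + lambda2 + lambda3."""
        return float(self.eigenvalues.sum())

    # -- persistence ---------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "n_samples": int(self.n_samples),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SporeColourModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(payload["mean"], dtype=float),
            eigenvalues=np.array(payload["eigenvalues"], dtype=float),
            eigenvectors=np.array(payload["eigenvectors"], dtype=float),
            n_samples=int(payload["n_samples"]),
        )


def _validate_pixels(samples: np.ndarray) -> np.ndarray:
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise FormatError("pixel samples must be an (n, 3) array of R,G,B values")
    if samples.size and (samples.min() < 0 or samples.max() > 255):
        raise FormatError("RGB intensities must lie in [0, 255]")
    return samples


def fit_colour_model(
    samples: np.ndarray, min_samples: int = DEFAULT_MIN_SAMPLES
) -> SporeColourModel:
    """Fit the spore colour distribution by PCA of the centred scatter.

    Parameters
    ----------
    samples : (n, 3) array-like
        RGB values of pixels known to lie inside spores.
    min_samples : int
        Minimum number of training pixels.

    Raises
    ------
    TrainingError
        Fewer than ``min_samples`` samples.
    DegenerateModelError
        All samples identical (rank-0 scatter).
    """
    samples = _validate_pixels(samples)
    n = samples.shape[0]
    if n < min_samples:
        raise TrainingError(f"need at least {min_samples} samples, got {n}")
    mean = samples.mean(axis=0)
    centred = samples - mean
    scatter = centred.T @ centred / n
    lam, vec = np.linalg.eigh(scatter)  # ascending
    lam = lam[::-1]
    vec = vec[:, ::-1].T  # rows v1, v2, v3
    if lam[0] <= 0.0:
        raise DegenerateModelError("training samples are identical; colour scatter has rank 0")
    lam = np.maximum(lam, EIGENVALUE_FLOOR * lam[0])
    # deterministic eigenvector signs: largest-magnitude component positive
    for i in range(3):
        j = int(np.argmax(np.abs(vec[i])))
        if vec[i, j] < 0:
            vec[i] = -vec[i]
    return SporeColourModel(mean=mean, eigenvalues=lam, eigenvectors=vec, n_samples=n)


def colour_score(model: SporeColourModel, pixel) -> float:
    """Mahalanobis colour-likelihood score of one RGB pixel (0 at the mean)."""
    p = np.asarray(pixel, dtype=float).reshape(3)
    c = model.eigenvectors @ (p - model.mean)
    return float(np.sum(c * c / model.eigenvalues))


def score_field(image: np.ndarray, model: SporeColourModel) -> np.ndarray:
    """Apply the colour score to every pixel of an RGB raster.

    Returns a float scalar field with the image's grid dimensions.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError("score_field expects an (H, W, 3) RGB image")
    centred = image.astype(float) - model.mean
    c = centred @ model.eigenvectors.T
    return np.einsum("hwk,k->hw", c * c, 1.0 / model.eigenvalues)


def classify_colour(field: np.ndarray, p1: float = DEFAULT_P1) -> np.ndarray:
    """Binary mask of pixels within the spore colour distribution (s < P1, strict)."""
    if p1 <= 0:
        raise ConfigError(f"P1 must be positive, got {p1}")
    return np.asarray(field) < p1


def load_pixel_csv(path: str | Path) -> np.ndarray:
    """Read a training-pixel table (columns ``r,g,b``, one pixel per row)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if not {"r", "g", "b"}.issubset(cols):
        raise FormatError("pixel CSV must have columns r,g,b")
    df.columns = cols
    return _validate_pixels(df[["r", "g", "b"]].to_numpy())


def harvest_from_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Collect training pixels from an image where a binary mask is true."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError("expected an (H, W, 3) RGB image")
    if mask.shape != image.shape[:2]:
        raise FormatError("mask shape must match the image grid")
    return image[mask].astype(float)
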