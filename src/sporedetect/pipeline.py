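"""Detection pipeline: colour scoring to validated spore candidates.

The chain follows the slide-analysis workflow: per-pixel colour score ->
colour classification (s < P1) -> least-squares gradient -> directional
averaging (offset P2) -> extreme-pixel mask (threshold P3) -> intersection of
the colour and extreme-pixel masks -> morphological closing (3 um disc) ->
connected components -> convex hull -> opening (2 um disc) -> conidium size
filter -> egg-shape fit -> outer-curve gradient-alignment and
background-correlation checks.  Every blob that reaches size filtering
becomes a :class:`SporeCandidate` with exactly one verdict.

Also provides the spore-trap tape arithmetic (six 4.9 cm pieces per 24 h
cycle, one transect per 2.0 mm representing 10 min, 144 transects per cycle)
and batch triage over image directories.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import blobs as blobmod
from . import colour as colourmod
from . import gradients as gradmod
from .blobs import AxisInfo, Blob, SizeBounds, PRIMARY_CONIDIA, SECONDARY_CONIDIA
from .colour import SporeColourModel
from .eggshape import (
    CheckResult,
    EggFit,
    FitConfig,
    background_correlation_check,
    egg_boundary,
    fit_egg,
    gradient_normal_check,
)
from .exceptions import ConfigError, FormatError
from .io import IMAGE_EXTENSIONS, read_image, write_image

DEFAULT_PIXEL_SIZE_UM = 0.5063

VERDICT_ACCEPTED = "accepted"
VERDICT_SIZE = "rejected_size"
VERDICT_FIT = "rejected_fit"
VERDICT_ALIGNMENT = "rejected_alignment"
VERDICT_CORRELATION = "rejected_correlation"


@dataclass(frozen=True)
class DetectionConfig:
    """All tunables of the detection chain, with documented defaults.

    P1 is the colour-score threshold (~3 sigma in 3 dimensions), P2 the
    sideways offset of the directional gradient average in pixels, P3 the
    averaged-gradient magnitude threshold.  P3 is data-product dependent;
    by default it is taken as a per-image quantile of the magnitude
    distribution (``p3_quantile``), with ``p3`` as an absolute override.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    p1: float = 9.0
    gradient_window_radius: int = 2
    p2_offset_px: float = 3.0
    p3: float | None = None
    p3_quantile: float = 0.99
    neighbourhood_side: int = 7
    top_fraction: float = 0.25
    closing_radius_um: float = 3.0
    opening_radius_um: float = 2.0
    colour_agreement_px: int = 3
    edge_bias_um: float = 1.0    # outward displacement of the gradient-crest ring
    size_bounds: SizeBounds = PRIMARY_CONIDIA
    fit_weight: float = 0.5
    max_fit_score: float = 2.0     # px; combined-score ceiling for a shape match
    outer_margin_um: float = 2.0
    alignment_min: float = 0.7
    correlation_max: float = 0.6
    connectivity: int = 8

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um", "p1", "p2_offset_px", "closing_radius_um",
            "opening_radius_um", "fit_weight", "max_fit_score",
            "outer_margin_um", "alignment_min",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.gradient_window_radius < 1:
            raise ConfigError("gradient_window_radius must be >= 1")
        if not 0 < self.p3_quantile < 1:
            raise ConfigError("p3_quantile must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectionConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "size_bounds" in payload:
            sb = payload["size_bounds"]
            if isinstance(sb, str):
                payload["size_bounds"] = {
                    "primary": PRIMARY_CONIDIA,
                    "secondary": SECONDARY_CONIDIA,
                }[sb]
            else:
                payload["size_bounds"] = SizeBounds(**sb)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass(frozen=True)
class SporeCandidate:
    """One size-filtered blob with its fit, checks and verdict."""

    blob: Blob
    axis: AxisInfo
    fit: EggFit | None
    alignment: CheckResult | None
    correlation: CheckResult | None
    verdict: str

    @property
    def accepted(self) -> bool:
        return self.verdict == VERDICT_ACCEPTED

    @property
    def center(self) -> np.ndarray:
        if self.fit is not None:
            return self.fit.pose.center
        return self.blob.centroid

    def report(self, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> dict:
        """JSON-serialisable summary of the candidate."""
        out: dict = {
            "verdict": self.verdict,
            "centroid_px": [float(v) for v in self.blob.centroid],
            "n_pixels": len(self.blob),
            "length_um": self.axis.length_um,
            "width_um": self.axis.width_um,
            "axis": [float(v) for v in self.axis.axis],
            "boundary_px": np.round(self.blob.boundary, 3).tolist(),
        }
        if self.fit is not None:
            f = self.fit
            out["egg_fit"] = {
                "a_px": f.shape.a,
                "b_px": f.shape.b,
                "a_um": f.shape.a * pixel_size_um,
                "b_um": f.shape.b * pixel_size_um,
                "c": f.shape.c,
                "center_px": [float(v) for v in f.pose.center],
                "theta_rad": f.pose.theta,
                "d_hausdorff_px": f.d_hausdorff,
                "d_l2_px3": f.d_l2,
                "score": f.score,
                "converged": f.converged,
                "n_evals": f.n_evals,
            }
        if self.alignment is not None:
            out["gradient_alignment"] = {
                "value": self.alignment.value, "valid": self.alignment.valid,
            }
        if self.correlation is not None:
            out["background_correlation"] = {
                "value": self.correlation.value, "valid": self.correlation.valid,
            }
        return out


def detect_spores(
    image: np.ndarray,
    model: SporeColourModel,
    config: DetectionConfig | None = None,
    return_debug: bool = False,
):
    """Run the full detection chain on one RGB image.

    Returns the list of :class:`SporeCandidate` (every blob that reached size
    filtering, with its verdict); with ``return_debug`` also returns a dict of
    intermediate fields (score field, masks, averaged gradient).
    """
    config = config or DetectionConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError("detect_spores expects an (H, W, 3) RGB image")

    score = colourmod.score_field(image, model)
    colour_mask = colourmod.classify_colour(score, config.p1)
    grad = gradmod.estimate_gradient(score, config.gradient_window_radius)
    avg = gradmod.directional_average(grad, config.p2_offset_px)
    mag = gradmod.gradient_magnitude(avg)
    p3 = config.p3 if config.p3 is not None else float(np.quantile(mag, config.p3_quantile))
    extreme = gradmod.extreme_pixel_mask(
        mag, p3, config.neighbourhood_side, config.top_fraction
    )
    # The extreme-pixel ridge of the score gradient straddles the colour
    # boundary, so a literal intersection of the two masks is near-empty;
    # require the edge and colour evidence to agree to within a few pixels
    # (the gradient-window/blur scale) instead.
    r = config.colour_agreement_px
    if r > 0:
        near_colour = ndimage.binary_dilation(
            colour_mask, structure=np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        )
    else:
        near_colour = colour_mask
    seg = near_colour & extreme
    closed = blobmod.close_mask(seg, config.closing_radius_um, config.pixel_size_um)
    components = blobmod.connected_components(closed, config.connectivity)

    fit_config = FitConfig(weight=config.fit_weight)
    candidates: list[SporeCandidate] = []
    for comp in components:
        hull = blobmod.convex_hull_blob(comp)
        pieces = blobmod.open_blob(hull, config.opening_radius_um, config.pixel_size_um)
        if config.edge_bias_um > 0:
            # the segmentation ring is centred on the score-gradient crest,
            # which lies outside the true region border by roughly the blur
            # scale; shrink blobs back by that offset before measuring
            pieces = [
                shrunk
                for piece in pieces
                for shrunk in blobmod.erode_blob(
                    piece, config.edge_bias_um, config.pixel_size_um
                )
            ]
        for piece in pieces:
            if len(piece) < 2:
                continue
            axis = blobmod.principal_axis(piece, config.pixel_size_um)
            if not blobmod.size_filter(axis, config.size_bounds):
                candidates.append(
                    SporeCandidate(piece, axis, None, None, None, VERDICT_SIZE)
                )
                continue
            fit = fit_egg(piece, fit_config)
            if not fit.converged or fit.score > config.max_fit_score:
                candidates.append(
                    SporeCandidate(piece, axis, fit, None, None, VERDICT_FIT)
                )
                continue
            alignment = gradient_normal_check(
                fit, avg, config.outer_margin_um, config.pixel_size_um
            )
            if alignment.valid and alignment.value < config.alignment_min:
                candidates.append(
                    SporeCandidate(piece, axis, fit, alignment, None, VERDICT_ALIGNMENT)
                )
                continue
            correlation = background_correlation_check(
                image, fit, config.outer_margin_um, config.pixel_size_um
            )
            if correlation.valid and correlation.value > config.correlation_max:
                candidates.append(
                    SporeCandidate(
                        piece, axis, fit, alignment, correlation, VERDICT_CORRELATION
                    )
                )
                continue
            candidates.append(
                SporeCandidate(piece, axis, fit, alignment, correlation, VERDICT_ACCEPTED)
            )

    if return_debug:
        debug = {
            "score": score,
            "colour_mask": colour_mask,
            "gradient": grad,
            "averaged_gradient": avg,
            "magnitude": mag,
            "p3": p3,
            "extreme_mask": extreme,
            "segmentation": seg,
            "closed_mask": closed,
        }
        return candidates, debug
    return candidates


# ---------------------------------------------------------------------------
# Spore-trap tape arithmetic


@dataclass(frozen=True)
class TapeLayout:
    """Spore-trap tape geometry and timing.

    One 24 h rotation is cut into six 4.9 cm pieces of 4 h each; manual
    transects are read every 2.0 mm, each representing 10 min, for 144
    transect readings per cycle.  (The printed tape length of 345 mm is not
    exactly six 49 mm pieces, and 345 mm / 144 is about 2.4 mm; the timing
    arithmetic here follows the 10-minutes-per-transect, 144-per-cycle
    reading.)
    """

    n_pieces: int = 6
    piece_length_cm: float = 4.9
    hours_per_piece: float = 4.0
    transect_interval_mm: float = 2.0
    minutes_per_transect: float = 10.0
    cycle_hours: float = 24.0

    def __post_init__(self) -> None:
        if not math.isclose(self.n_pieces * self.hours_per_piece, self.cycle_hours):
            raise ConfigError("n_pieces * hours_per_piece must equal cycle_hours")


def total_transects(layout: TapeLayout | None = None) -> int:
    """Number of transect readings in one full cycle."""
    layout = layout or TapeLayout()
    return int(round(layout.cycle_hours * 60.0 / layout.minutes_per_transect))


def transect_time(index: int, layout: TapeLayout | None = None) -> float:
    """Minutes from cycle start to the given transect (0-based index)."""
    layout = layout or TapeLayout()
    n = total_transects(layout)
    if not 0 <= index < n:
        raise ConfigError(f"transect index {index} out of range [0, {n})")
    return index * layout.minutes_per_transect


# ---------------------------------------------------------------------------
# Batch processing and overlays


@dataclass(frozen=True)
class BatchReport:
    rows: list[dict]            # per image: name, n_candidates, n_accepted
    flagged: list[str]          # images with >= 1 accepted candidate
    skipped: list[str]          # unreadable files


def batch_process(
    directory: str | Path,
    model: SporeColourModel,
    config: DetectionConfig | None = None,
    out_dir: str | Path | None = None,
    overlay: bool = False,
) -> BatchReport:
    """Detect spores in every image of a directory (sorted by filename).

    Writes, when ``out_dir`` is given: one JSON report per image, a
    ``summary.csv`` (image, n_candidates, n_accepted) and a ``flagged.txt``
    listing images with at least one accepted candidate.  Unreadable files
    are logged and skipped, never aborting the batch.
    """
    config = config or DetectionConfig()
    directory = Path(directory)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    flagged: list[str] = []
    skipped: list[str] = []
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )
    for path in files:
        try:
            image = read_image(path)
            candidates = detect_spores(image, model, config)
        except FormatError:
            skipped.append(path.name)
            continue
        n_acc = sum(c.accepted for c in candidates)
        rows.append(
            {"image": path.name, "n_candidates": len(candidates), "n_accepted": n_acc}
        )
        if n_acc > 0:
            flagged.append(path.name)
        if out_path is not None:
            report = {
                "image": path.name,
                "candidates": [c.report(config.pixel_size_um) for c in candidates],
            }
            (out_path / f"{path.stem}.json").write_text(json.dumps(report, indent=2))
            if overlay:
                write_image(
                    out_path / f"{path.stem}_overlay.png",
                    write_overlay(image, candidates),
                )
    if out_path is not None:
        with open(out_path / "summary.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["image", "n_candidates", "n_accepted"])
            writer.writeheader()
            writer.writerows(rows)
        (out_path / "flagged.txt").write_text("".join(f"{n}\n" for n in flagged))
        if skipped:
            (out_path / "skipped.txt").write_text("".join(f"{n}\n" for n in skipped))
    return BatchReport(rows=rows, flagged=flagged, skipped=skipped)


ACCEPTED_COLOUR = (0, 200, 0)
REJECTED_COLOUR = (220, 40, 40)


def write_overlay(image: np.ndarray, candidates: list[SporeCandidate]) -> np.ndarray:
    """Draw fitted egg outlines (accepted green, rejected red) and axes."""
    from skimage.draw import line as draw_line
    from skimage.draw import polygon_perimeter

    out = np.asarray(image, dtype=np.uint8).copy()
    h, w = out.shape[:2]
    for cand in candidates:
        colour = ACCEPTED_COLOUR if cand.accepted else REJECTED_COLOUR
        if cand.fit is not None:
            poly = egg_boundary(cand.fit.shape, cand.fit.pose, 512)
            rr, cc = polygon_perimeter(
                np.clip(np.rint(poly[:, 1]), 0, h - 1).astype(int),
                np.clip(np.rint(poly[:, 0]), 0, w - 1).astype(int),
                shape=out.shape[:2],
            )
            out[rr, cc] = colour
            cx, cy = cand.fit.pose.center
            th = cand.fit.pose.theta
            a = cand.fit.shape.a
            x0 = int(np.clip(round(cx - a * math.cos(th)), 0, w - 1))
            y0 = int(np.clip(round(cy - a * math.sin(th)), 0, h - 1))
            x1 = int(np.clip(round(cx + a * math.cos(th)), 0, w - 1))
            y1 = int(np.clip(round(cy + a * math.sin(th)), 0, h - 1))
            rr, cc = draw_line(y0, x0, y1, x1)
            out[rr, cc] = colour
        else:
            poly = cand.blob.boundary
            rr, cc = polygon_perimeter(
                np.clip(np.rint(poly[:, 1]), 0, h - 1).astype(int),
                np.clip(np.rint(poly[:, 0]), 0, w - 1).astype(int),
                shape=out.shape[:2],
            )
            out[rr, cc] = colour
    return out
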