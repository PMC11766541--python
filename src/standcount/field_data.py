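"""Field imagery, plant annotations and raster masks on the common cm grid.

Everything downstream of this module works at a fixed scale of 1 px = 1 cm.
Coordinates are (x, y) in cm with the origin at the top-left pixel corner,
x rightward and y downward; pixel (i, j) covers the half-open cell
[j, j+1) x [i, i+1) cm, so its center sits at (j + 0.5, i + 0.5).
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize

from .errors import EstimationError, ScaleError, ValidationError

log = logging.getLogger(__name__)

AnnotationSource = Literal["manual_point", "box_derived", "synthetic"]


@dataclass
class Orthomosaic:
    """An RGB field image with an optional ground sampling distance (cm/px)."""

    pixels: np.ndarray
    gsd_cm_per_px: float | None = None
    crs_tag: str | None = None  # carried through opaquely, never interpreted

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("pixels: expected an HxWx3 RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("pixels: H and W must be >= 1")
        if self.gsd_cm_per_px is not None and not self.gsd_cm_per_px > 0:
            raise ValidationError("gsd_cm_per_px: must be positive when present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class PlantAnnotation:
    """Plant center points in cm, with optional source bounding boxes."""

    centers: list[tuple[float, float]]
    source: AnnotationSource = "manual_point"
    boxes: list[tuple[float, float, float, float]] | None = None

    def __post_init__(self) -> None:
        self.centers = [(float(x), float(y)) for x, y in self.centers]
        if not all(np.isfinite(c).all() for c in map(np.asarray, self.centers)):
            raise ValidationError("centers: all coordinates must be finite")

    def __len__(self) -> int:
        return len(self.centers)

    def as_array(self) -> np.ndarray:
        if not self.centers:
            return np.empty((0, 2), dtype=float)
        return np.asarray(self.centers, dtype=float)


@dataclass
class RasterMask:
    """Binary plant-presence raster at 1 px = 1 cm: background 0, plants 255."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels: mask must be single-channel (HxW)")
        bad = set(np.unique(self.pixels)) - {0, 255}
        if bad:
            raise ValidationError(f"pixels: mask values must be in {{0, 255}}, found {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground(self) -> np.ndarray:
        return self.pixels == 255


@dataclass
class TileGrid:
    """A regular non-overlapping tiling, row-major offset order."""

    tile_h_px: int
    tile_w_px: int
    coverage: Literal["drop_partial", "pad_partial"] = "drop_partial"

    def __post_init__(self) -> None:
        if self.tile_h_px < 1 or self.tile_w_px < 1:
            raise ValidationError("tile dims: must be >= 1")
        if self.coverage not in ("drop_partial", "pad_partial"):
            raise ValidationError("coverage: must be drop_partial or pad_partial")

    def offsets(self, shape: tuple[int, int]) -> list[tuple[int, int]]:
        h, w = shape
        if self.coverage == "drop_partial":
            rows = range(0, h - self.tile_h_px + 1, self.tile_h_px)
            cols = range(0, w - self.tile_w_px + 1, self.tile_w_px)
        else:
            rows = range(0, h, self.tile_h_px)
            cols = range(0, w, self.tile_w_px)
        return [(r, c) for r in rows for c in cols]


# ---------------------------------------------------------------------------
# operations


def normalize_scale(
    image: Orthomosaic,
    target_cm_per_px: float = 1.0,
    annotation: PlantAnnotation | None = None,
):
    """Resample an orthomosaic to the working scale (default 1 px = 1 cm).

    Returns the rescaled image, or a ``(image, annotation)`` pair when an
    annotation is passed alongside (point coordinates are multiplied by the
    same factor; at the target scale cm coordinates are pixel coordinates).
    """
    if image.gsd_cm_per_px is None:
        raise ScaleError(
            "ground sampling distance unknown; estimate it first, e.g. with "
            "infer_scale_from_rows using a known row spacing"
        )
    factor = image.gsd_cm_per_px / target_cm_per_px
    h, w = image.shape
    out_h, out_w = int(round(h * factor)), int(round(w * factor))
    if factor == 1.0:
        out = Orthomosaic(image.pixels.copy(), target_cm_per_px, image.crs_tag)
    else:
        resized = resize(
            image.pixels, (out_h, out_w), order=1, preserve_range=True,
            anti_aliasing=factor < 1.0,
        )
        out = Orthomosaic(
            np.clip(np.rint(resized), 0, 255).astype(np.uint8),
            target_cm_per_px,
            image.crs_tag,
        )
    if annotation is None:
        return out
    scaled = PlantAnnotation(
        [(x * factor, y * factor) for x, y in annotation.centers],
        source=annotation.source,
    )
    return out, scaled


def infer_scale_from_rows(
    annotation: PlantAnnotation, known_row_spacing_cm: float
) -> float:
    """Estimate cm/px from the pixel-unit spacing of crop rows.

    The dominant row direction is the principal axis of the center cloud;
    rows are the clusters of the projections onto the orthogonal axis, and the
    spacing estimate is the median gap between adjacent row clusters.
    """
    pts = annotation.as_array()
    if len(pts) < 10:
        raise EstimationError(
            f"need at least 10 centers to infer scale, got {len(pts)}"
        )
    if not known_row_spacing_cm > 0:
        raise ValidationError("known_row_spacing_cm: must be positive")
    centered = pts - pts.mean(axis=0)
    # scan candidate across-row directions: the correct one collapses the
    # projections into few tight clusters, giving a large normalized maximum
    # gap; along-row (or oblique) projections spread quasi-uniformly
    best = None
    for theta in np.deg2rad(np.arange(0.0, 180.0, 1.0)):
        axis = np.array([np.cos(theta), np.sin(theta)])
        proj = np.sort(centered @ axis)
        spread = proj[-1] - proj[0]
        if spread <= 0:
            continue
        gaps = np.diff(proj)
        score = gaps.max() / spread
        if best is None or score > best[0]:
            best = (score, proj, gaps)
    if best is None or best[0] < 0.08:
        raise EstimationError(
            "no periodic row structure detected in the projected centers "
            f"(best clustering score {0.0 if best is None else best[0]:.3f})"
        )
    _, proj, gaps = best
    # between-row gaps dominate within-row scatter; split at half the max gap
    thresh = 0.5 * gaps.max()
    labels = np.concatenate([[0], np.cumsum(gaps > thresh)])
    row_pos = np.array([proj[labels == k].mean() for k in range(labels.max() + 1)])
    if len(row_pos) < 2:
        raise EstimationError("fewer than 2 rows detected")
    if len(row_pos) > 0.6 * len(pts):
        # clusters are mostly singletons: points are not grouped into rows
        raise EstimationError("no row grouping detected (clusters are singletons)")
    spacing_px = float(np.median(np.diff(row_pos)))
    return known_row_spacing_cm / spacing_px


def rasterize_centers(
    annotation: PlantAnnotation | Iterable[tuple[float, float]],
    shape: tuple[int, int],
    radius_cm: float = 4.0,
) -> RasterMask:
    """Paint a disc of ``radius_cm`` at every plant center.

    A pixel is foreground when its center lies within ``radius_cm`` of the
    annotation point; overlapping discs merge, out-of-bounds parts are clipped.
    """
    h, w = shape
    if h < 1 or w < 1:
        raise ValidationError("shape: must be positive")
    if not radius_cm > 0:
        raise ValidationError("radius_cm: must be positive")
    centers = annotation.centers if isinstance(annotation, PlantAnnotation) else list(annotation)
    out = np.zeros((h, w), dtype=np.uint8)
    r2 = radius_cm * radius_cm
    for x, y in centers:
        j0 = max(int(np.floor(x - radius_cm - 1)), 0)
        j1 = min(int(np.ceil(x + radius_cm + 1)), w)
        i0 = max(int(np.floor(y - radius_cm - 1)), 0)
        i1 = min(int(np.ceil(y + radius_cm + 1)), h)
        if j0 >= j1 or i0 >= i1:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        inside = (jj + 0.5 - x) ** 2 + (ii + 0.5 - y) ** 2 <= r2
        out[i0:i1, j0:j1][inside] = 255
    return RasterMask(out)


def boxes_to_centers(
    boxes: Sequence[tuple[float, float, float, float]]
) -> PlantAnnotation:
    """Convert bounding boxes to their midpoints (the box-derived markup style)."""
    centers = []
    kept_boxes = []
    for b in boxes:
        x_min, y_min, x_max, y_max = map(float, b)
        if x_min > x_max or y_min > y_max:
            raise ValidationError(f"box {b}: min must not exceed max per axis")
        if x_min == x_max or y_min == y_max:
            warnings.warn(f"degenerate zero-area box {b}", stacklevel=2)
        centers.append(((x_min + x_max) / 2.0, (y_min + y_max) / 2.0))
        kept_boxes.append((x_min, y_min, x_max, y_max))
    return PlantAnnotation(centers, source="box_derived", boxes=kept_boxes or None)


def tile_image(
    image: np.ndarray | Orthomosaic | RasterMask, grid: TileGrid
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Cut an image or mask into grid tiles; returns ``[((row0, col0), tile), ...]``.

    With ``drop_partial`` only fully interior tiles are returned; with
    ``pad_partial`` edge tiles are zero-padded to full size.
    """
    if isinstance(image, (Orthomosaic, RasterMask)):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    h, w = arr.shape[:2]
    th, tw = grid.tile_h_px, grid.tile_w_px
    if grid.coverage == "drop_partial" and (th > h or tw > w):
        warnings.warn(
            f"tile {th}x{tw} larger than image {h}x{w}; no tiles produced",
            stacklevel=2,
        )
        return []
    tiles = []
    for r0, c0 in grid.offsets((h, w)):
        tile = arr[r0 : r0 + th, c0 : c0 + tw]
        if tile.shape[0] < th or tile.shape[1] < tw:
            pad = [(0, th - tile.shape[0]), (0, tw - tile.shape[1])]
            pad += [(0, 0)] * (arr.ndim - 2)
            tile = np.pad(tile, pad)
        tiles.append(((r0, c0), tile))
    return tiles


# ---------------------------------------------------------------------------
# file I/O


def read_image(path: str | Path) -> Orthomosaic:
    """Read a PNG/TIFF RGB image; the GSD must be supplied or inferred separately."""
    arr = np.asarray(Image.open(path).convert("RGB"))
    return Orthomosaic(arr)


def write_image(image: Orthomosaic | np.ndarray, path: str | Path) -> None:
    arr = image.pixels if isinstance(image, Orthomosaic) else np.asarray(image)
    Image.fromarray(arr).save(path)


def read_mask(path: str | Path) -> RasterMask:
    arr = np.asarray(Image.open(path).convert("L"))
    # tolerate near-binary encodings: anything > 127 is foreground
    return RasterMask(np.where(arr > 127, 255, 0).astype(np.uint8))


def write_mask(mask: RasterMask, path: str | Path) -> None:
    Image.fromarray(mask.pixels, mode="L").save(path)


def read_centers_csv(path: str | Path) -> PlantAnnotation:
    """Read centers from a two-column ``x_cm,y_cm`` CSV (header required)."""
    centers = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            centers.append((float(row["x_cm"]), float(row["y_cm"])))
    return PlantAnnotation(centers)


def write_centers_csv(annotation: PlantAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_cm", "y_cm"])
        writer.writerows(annotation.centers)


def read_boxes_csv(path: str | Path) -> PlantAnnotation:
    boxes = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            boxes.append(
                (float(row["x_min"]), float(row["y_min"]),
                 float(row["x_max"]), float(row["y_max"]))
            )
    return boxes_to_centers(boxes)


def read_centers_geojson(path: str | Path) -> PlantAnnotation:
    with open(path) as fh:
        doc = json.load(fh)
    centers = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") == "Point":
            x, y = geom["coordinates"][:2]
            centers.append((float(x), float(y)))
    return PlantAnnotation(centers)


def write_centers_geojson(annotation: PlantAnnotation, path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {},
            }
            for x, y in annotation.centers
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
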