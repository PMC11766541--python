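"""Plant counting from a binary mask: components, noise filter, centroids.

A plant is a maximal 8-connected foreground component of the predicted mask.
Components smaller than ``min_area_px`` are discarded as segmentation noise
(speckle between rows); the survivors are reported with centroid, bounding
box and outer contour, and the stand count is simply their number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .errors import ValidationError
from .field_data import RasterMask


@dataclass(frozen=True)
class CountFilterConfig:
    min_area_px: int = 10
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_area_px < 0:
            raise ValidationError("min_area_px: must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity: must be 4 or 8")


@dataclass
class PlantRegion:
    centroid: tuple[float, float]  # (x_cm, y_cm)
    area_px: int
    bbox: tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max) cm
    contour: np.ndarray = field(repr=False)  # ordered (x, y) boundary points


def extract_plants(
    mask: RasterMask | np.ndarray, config: CountFilterConfig = CountFilterConfig()
) -> list[PlantRegion]:
    """Extract filtered plant regions, sorted by (y, x) of centroid."""
    arr = mask.pixels if isinstance(mask, RasterMask) else np.asarray(mask)
    fg = arr > 0
    labels = measure.label(fg, connectivity=2 if config.connectivity == 8 else 1)
    regions: list[PlantRegion] = []
    for rp in measure.regionprops(labels):
        if rp.area < config.min_area_px:
            continue
        cy, cx = rp.centroid  # row/col means of member pixels
        # pixel (i, j) covers [j, j+1) x [i, i+1) cm; its center is (+0.5, +0.5)
        centroid = (float(cx) + 0.5, float(cy) + 0.5)
        r0, c0, r1, c1 = rp.bbox
        region_img = np.pad(rp.image.astype(float), 1)
        cont = measure.find_contours(region_img, 0.5)
        if cont:
            outer = max(cont, key=len)
            contour = np.column_stack(
                [outer[:, 1] - 1 + c0 + 0.5, outer[:, 0] - 1 + r0 + 0.5]
            )
        else:  # pragma: no cover - single pixel always yields a contour
            contour = np.array([centroid])
        regions.append(
            PlantRegion(
                centroid=centroid,
                area_px=int(rp.area),
                bbox=(float(c0), float(r0), float(c1), float(r1)),
                contour=contour,
            )
        )
    regions.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return regions


def count_plants(
    mask: RasterMask | np.ndarray, config: CountFilterConfig = CountFilterConfig()
) -> int:
    return len(extract_plants(mask, config))


def plant_density(count: int, area_m2: float) -> float:
    """Plants per hectare from a count over ``area_m2`` square meters."""
    if not area_m2 > 0:
        raise ValidationError("area_m2: must be positive")
    return count / area_m2 * 10_000.0


def write_regions_csv(regions: list[PlantRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id,x_cm,y_cm,area_px\n")
        for i, r in enumerate(regions):
            fh.write(f"{i},{r.centroid[0]:.3f},{r.centroid[1]:.3f},{r.area_px}\n")


def write_count_summary(regions: list[PlantRegion], area_m2: float, path: str | Path) -> None:
    summary = {
        "count": len(regions),
        "density_per_ha": plant_density(len(regions), area_m2) if area_m2 > 0 else None,
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
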