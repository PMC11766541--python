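"""Agreement metrics between a manual and a predicted markup.

Pixel-level quality is intersection-over-union of the two binary masks.
Count-level quality compares per-tile plant counts over a non-overlapping
grid: MAE, MAPE, Pearson r and Spearman r_s.  Following the source method's
printed formula, MAPE divides by the *predicted* count y_i,

    MAE  = (1/n) sum |x_i - y_i|,
    MAPE = (100/n) sum |x_i - y_i| / y_i,

which is deliberately not the conventional reference-denominator MAPE; a
switch is provided for the conventional form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .field_data import RasterMask, TileGrid, tile_image
from .stand_counting import CountFilterConfig, count_plants

log = logging.getLogger(__name__)


@dataclass
class CountSeries:
    """Per-tile counts from markup A (manual, x) and markup B (predicted, y)."""

    x: list[int]
    y: list[int]
    tile_size_m: float = 20.0

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValidationError("x/y: series must have equal length")
        if len(self.x) < 1:
            raise ValidationError("x/y: need at least one tile")
        if any(v < 0 for v in self.x) or any(v < 0 for v in self.y):
            raise ValidationError("counts: must be non-negative")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class EvalReport:
    mae: float
    mape_pct: float  # NaN when undefined (some y_i = 0)
    pearson_r: float
    spearman_rs: float
    pixel_iou: float | None = None

    def as_dict(self) -> dict:
        return {
            "MAE": self.mae,
            "MAPE_pct": self.mape_pct,
            "r": self.pearson_r,
            "r_s": self.spearman_rs,
            "IoU": self.pixel_iou,
        }


def pixel_iou(mask_a: RasterMask | np.ndarray, mask_b: RasterMask | np.ndarray) -> float:
    """|A n B| / |A u B| over foreground pixels; 1.0 when both masks are empty."""
    a = (mask_a.pixels if isinstance(mask_a, RasterMask) else np.asarray(mask_a)) > 0
    b = (mask_b.pixels if isinstance(mask_b, RasterMask) else np.asarray(mask_b)) > 0
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def tile_counts(
    mask: RasterMask,
    grid: TileGrid,
    filter: CountFilterConfig = CountFilterConfig(),
) -> list[int]:
    """Per-tile plant counts in row-major tile order.

    A region straddling a tile boundary is counted in every tile it touches,
    so the tile sum can exceed the whole-mask count.
    """
    return [count_plants(tile, filter) for _, tile in tile_image(mask, grid)]


def count_metrics(
    series: CountSeries,
    mape_denominator: Literal["predicted", "manual"] = "predicted",
) -> EvalReport:
    """MAE/MAPE and rank/linear correlations of two count series."""
    x = np.asarray(series.x, dtype=float)
    y = np.asarray(series.y, dtype=float)
    mae = float(np.mean(np.abs(x - y)))

    denom = y if mape_denominator == "predicted" else x
    if np.any(denom == 0):
        zero_both = (x == 0) & (y == 0)
        usable = denom != 0
        if np.all(zero_both[~usable]):
            # tiles empty in both markups carry no percentage information
            log.info("MAPE: excluding %d tiles empty in both series", (~usable).sum())
        else:
            warnings.warn(
                "MAPE undefined: denominator series contains zero counts",
                stacklevel=2,
            )
        if usable.sum() == 0 or not np.all(zero_both[~usable]):
            mape = float("nan")
        else:
            mape = float(100.0 * np.mean(np.abs(x[usable] - y[usable]) / denom[usable]))
    else:
        mape = float(100.0 * np.mean(np.abs(x - y) / denom))

    if series.n < 2 or np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("correlations undefined for constant or length-1 series",
                      stacklevel=2)
        r = rs = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
        rs = float(stats.spearmanr(x, y).statistic)
    return EvalReport(mae=mae, mape_pct=mape, pearson_r=r, spearman_rs=rs)


def evaluate_masks(
    truth: RasterMask,
    pred: RasterMask,
    tile_px: int = 2000,
    filter: CountFilterConfig = CountFilterConfig(),
    mape_denominator: Literal["predicted", "manual"] = "predicted",
) -> EvalReport:
    """Full report: pixel IoU plus tile-count metrics on a shared grid.

    ``tile_px`` defaults to 2000 (a 20 m x 20 m tile at 1 px = 1 cm) and is
    configurable for desk-scale scenes.
    """
    if truth.shape != pred.shape:
        raise ValidationError("truth/pred masks must share shape")
    grid = TileGrid(tile_px, tile_px, "drop_partial")
    series = CountSeries(
        x=tile_counts(truth, grid, filter),
        y=tile_counts(pred, grid, filter),
        tile_size_m=tile_px / 100.0,
    )
    report = count_metrics(series, mape_denominator)
    report.pixel_iou = pixel_iou(truth, pred)
    return report
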