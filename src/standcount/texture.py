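"""Second-order texture statistics of plant masks and markup comparison.

Cropping patterns (row spacing, sowing regularity, merged or missing plants)
leave a signature in the spatial statistics of the binary plant mask.  Two
classical constructions are used, each evaluated along the 8 unit directions
(up, down, left, right and the four diagonals) and averaged:

* the gray-level co-occurrence matrix (GLCM): the joint distribution of pixel
  values at a fixed unit displacement, summarized by its mean and correlation;
* the gray-level run-length matrix (GLRM): counts of maximal constant-value
  runs by level and length, summarized by long-run emphasis
  (sum R[l,j] * j^2 / n_runs) and run percentage (n_runs / n_pixels).

Gray levels are the native pixel values without re-quantization; for binary
masks these are {0, 255}.  Opposite displacements are both members of the
direction set, so averaging over the 8 directions symmetrizes the GLCM
features without per-matrix symmetrization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .field_data import RasterMask, TileGrid, tile_image

log = logging.getLogger(__name__)

#: the 8 unit displacements (dy, dx): axial then diagonal
DIRECTIONS: tuple[tuple[int, int], ...] = (
    (-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1),
)


@dataclass
class GLCMatrix:
    levels: np.ndarray  # sorted distinct gray values present
    P: np.ndarray       # levels x levels co-occurrence probabilities
    displacement: tuple[int, int]


@dataclass
class GLRMatrix:
    levels: np.ndarray
    R: np.ndarray       # levels x max_run, R[l, j] = count of runs of length j+1
    n_runs: int
    n_pixels: int
    direction: tuple[int, int]


def glcm(tile: np.ndarray, displacement: tuple[int, int]) -> GLCMatrix:
    """Co-occurrence probabilities of pixel pairs ``(p, p + d)`` inside the tile."""
    tile = np.asarray(tile)
    if tile.ndim != 2 or tile.size == 0:
        raise ValidationError("tile: must be a non-empty 2-D array")
    dy, dx = displacement
    if displacement not in DIRECTIONS:
        raise ValidationError(f"displacement {displacement}: must be one of the 8 unit vectors")
    h, w = tile.shape
    if h - abs(dy) < 1 or w - abs(dx) < 1:
        raise ValidationError("tile smaller than 2 px in the displacement direction")
    levels, idx = np.unique(tile, return_inverse=True)
    idx = idx.reshape(tile.shape)
    src = idx[max(-dy, 0) : h - max(dy, 0), max(-dx, 0) : w - max(dx, 0)]
    dst = idx[max(dy, 0) : h - max(-dy, 0), max(dx, 0) : w - max(-dx, 0)]
    n_levels = len(levels)
    counts = np.bincount(
        (src.ravel() * n_levels + dst.ravel()), minlength=n_levels * n_levels
    ).reshape(n_levels, n_levels)
    total = counts.sum()
    return GLCMatrix(levels=levels.astype(float), P=counts / total, displacement=displacement)


def glcm_features(m: GLCMatrix) -> tuple[float, float]:
    """(mean, correlation); correlation is NaN when either marginal is constant."""
    px = m.P.sum(axis=1)
    py = m.P.sum(axis=0)
    mu_x = float(np.dot(m.levels, px))
    mu_y = float(np.dot(m.levels, py))
    var_x = float(np.dot((m.levels - mu_x) ** 2, px))
    var_y = float(np.dot((m.levels - mu_y) ** 2, py))
    if var_x <= 0 or var_y <= 0:
        return mu_x, float("nan")
    cov = float(((m.levels[:, None] - mu_x) * (m.levels[None, :] - mu_y) * m.P).sum())
    return mu_x, cov / np.sqrt(var_x * var_y)


def _lines_for_direction(tile: np.ndarray, direction: tuple[int, int]):
    """Yield the scan lines of a tile for one of the 8 directions.

    Opposite directions traverse the same lines in reverse, which leaves the
    set of maximal runs unchanged; lines are yielded in canonical order.
    """
    h, w = tile.shape
    dy, dx = direction
    if dy == 0:          # left/right: rows
        yield from tile
    elif dx == 0:        # up/down: columns
        yield from tile.T
    elif dy == dx:       # main diagonals
        for off in range(-(h - 1), w):
            yield np.diagonal(tile, offset=off)
    else:                # anti-diagonals
        flipped = tile[::-1]
        for off in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=off)


def glrm(tile: np.ndarray, direction: tuple[int, int]) -> GLRMatrix:
    """Run-length matrix: counts of maximal equal-value runs along a direction."""
    tile = np.asarray(tile)
    if tile.ndim != 2 or tile.size == 0:
        raise ValidationError("tile: must be a non-empty 2-D array")
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction {direction}: must be one of the 8 unit vectors")
    levels, idx = np.unique(tile, return_inverse=True)
    idx = idx.reshape(tile.shape)
    run_levels: list[np.ndarray] = []
    run_lengths: list[np.ndarray] = []
    for line in _lines_for_direction(idx, direction):
        if line.size == 0:
            continue
        change = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [line.size]])
        run_levels.append(line[starts])
        run_lengths.append(ends - starts)
    lv = np.concatenate(run_levels)
    ln = np.concatenate(run_lengths)
    max_run = int(ln.max())
    R = np.zeros((len(levels), max_run), dtype=np.int64)
    np.add.at(R, (lv, ln - 1), 1)
    return GLRMatrix(
        levels=levels.astype(float), R=R, n_runs=int(len(lv)),
        n_pixels=int(tile.size), direction=direction,
    )


def glrm_features(m: GLRMatrix) -> tuple[float, float]:
    """(long-run emphasis, run percentage)."""
    if m.n_runs < 1:
        raise ValidationError("empty run-length matrix")
    lengths = np.arange(1, m.R.shape[1] + 1)
    long_run = float((m.R * lengths[None, :] ** 2).sum() / m.n_runs)
    run_ratio = m.n_runs / m.n_pixels
    return long_run, run_ratio


def tile_texture_features(tile: np.ndarray) -> dict[str, float]:
    """The four direction-averaged features of one tile.

    GLCM correlation is NaN for tiles where it is undefined in every
    direction (e.g. constant tiles).
    """
    glcm_means, glcm_corrs, long_runs, run_ratios = [], [], [], []
    for d in DIRECTIONS:
        mean, corr = glcm_features(glcm(tile, d))
        glcm_means.append(mean)
        glcm_corrs.append(corr)
        lre, rp = glrm_features(glrm(tile, d))
        long_runs.append(lre)
        run_ratios.append(rp)
    corrs = np.asarray(glcm_corrs)
    defined = corrs[~np.isnan(corrs)]
    return {
        "glcm_mean": float(np.mean(glcm_means)),
        "glcm_correlation": float(np.mean(defined)) if len(defined) == len(corrs) else float("nan"),
        "glrm_long_run": float(np.mean(long_runs)),
        "glrm_run_ratio": float(np.mean(run_ratios)),
    }


FEATURES = ("glcm_mean", "glcm_correlation", "glrm_long_run", "glrm_run_ratio")


def texture_profile(mask: RasterMask | np.ndarray, grid: TileGrid | None = None) -> pd.DataFrame:
    """Per-tile texture features of a mask over a non-overlapping grid.

    Default grid: 1000 x 1000 px tiles (10 m x 10 m at 1 px = 1 cm), partial
    edge tiles dropped.  Returns a DataFrame with columns tile_id, row0,
    col0, the four features, and a ``constant`` flag for degenerate tiles.
    """
    arr = mask.pixels if isinstance(mask, RasterMask) else np.asarray(mask)
    if grid is None:
        grid = TileGrid(1000, 1000, "drop_partial")
    rows = []
    for tid, ((r0, c0), tile) in enumerate(tile_image(arr, grid)):
        feats = tile_texture_features(tile)
        rows.append(
            {"tile_id": tid, "row0": r0, "col0": c0, **feats,
             "constant": bool(len(np.unique(tile)) == 1)}
        )
    return pd.DataFrame(rows)


def compare_markups(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    paired_test: Literal["t", "wilcoxon"] = "t",
) -> pd.DataFrame:
    """Tile-paired comparison of two texture profiles (manual A vs predicted B).

    Per feature: means, mean difference (B - A), a paired two-sided test,
    the OLS fit of B on A (slope/intercept; manual markup on the X axis) and
    Pearson r.  Tiles with an undefined feature in either profile are dropped
    pairwise; the number dropped is reported per feature.
    """
    merged = profile_a.merge(profile_b, on="tile_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValidationError("need >= 3 common tiles to compare markups")
    out = []
    for feat in FEATURES:
        a = merged[f"{feat}_a"].to_numpy(dtype=float)
        b = merged[f"{feat}_b"].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        n_dropped = int((~ok).sum())
        a, b = a[ok], b[ok]
        if len(a) < 3:
            raise ValidationError(
                f"feature {feat}: fewer than 3 tiles with defined values"
            )
        if paired_test == "t":
            p = float(stats.ttest_rel(a, b).pvalue) if np.any(a != b) else 1.0
        else:
            p = float(stats.wilcoxon(a, b).pvalue) if np.any(a != b) else 1.0
        if np.all(a == a[0]):
            slope, intercept, r = float("nan"), float("nan"), float("nan")
        else:
            fit = stats.linregress(a, b)
            slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
        out.append(
            {
                "feature": feat,
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "mean_diff": float(np.mean(b) - np.mean(a)),
                "paired_test_p": p,
                "slope": slope,
                "intercept": intercept,
                "pearson_r": r,
                "n_tiles": int(len(a)),
                "n_dropped": n_dropped,
            }
        )
    return pd.DataFrame(out)
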