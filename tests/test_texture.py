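"""GLCM/GLRM construction and features against exhaustive enumeration."""

import numpy as np
import pandas as pd
import pytest

from standcount.errors import ValidationError
from standcount.field_data import TileGrid, rasterize_centers
from standcount.synthetic_fields import FieldSpec, generate_field
from standcount.texture import (
    DIRECTIONS,
    compare_markups,
    glcm,
    glcm_features,
    glrm,
    glrm_features,
    texture_profile,
    tile_texture_features,
)


# --- brute-force oracles ----------------------------------------------------

def oracle_glcm(tile, d):
    """Exhaustive pair enumeration."""
    dy, dx = d
    h, w = tile.shape
    levels = sorted(set(tile.ravel().tolist()))
    index = {v: i for i, v in enumerate(levels)}
    P = np.zeros((len(levels), len(levels)))
    n = 0
    for i in range(h):
        for j in range(w):
            ii, jj = i + dy, j + dx
            if 0 <= ii < h and 0 <= jj < w:
                P[index[tile[i, j]], index[tile[ii, jj]]] += 1
                n += 1
    return np.array(levels, dtype=float), P / n


def oracle_glcm_features(levels, P):
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = sum(l * p for l, p in zip(levels, px))
    my = sum(l * p for l, p in zip(levels, py))
    vx = sum((l - mx) ** 2 * p for l, p in zip(levels, px))
    vy = sum((l - my) ** 2 * p for l, p in zip(levels, py))
    if vx <= 0 or vy <= 0:
        return mx, float("nan")
    cov = 0.0
    for a in range(len(levels)):
        for b in range(len(levels)):
            cov += (levels[a] - mx) * (levels[b] - my) * P[a, b]
    return mx, cov / (vx * vy) ** 0.5


def oracle_runs(tile, d):
    """Line-by-line scan for maximal runs; returns dict {(value, length): count}."""
    dy, dx = d
    h, w = tile.shape
    # collect scan lines for the direction family
    lines = []
    if dy == 0:
        lines = [list(tile[i, :]) for i in range(h)]
    elif dx == 0:
        lines = [list(tile[:, j]) for j in range(w)]
    elif dy == dx:
        for off in range(-(h - 1), w):
            lines.append([tile[i, i + off] for i in range(max(0, -off), min(h, w - off))])
    else:
        fl = tile[::-1]
        for off in range(-(h - 1), w):
            lines.append([fl[i, i + off] for i in range(max(0, -off), min(h, w - off))])
    counts: dict = {}
    for line in lines:
        k = 0
        while k < len(line):
            m = k
            while m + 1 < len(line) and line[m + 1] == line[k]:
                m += 1
            counts[(line[k], m - k + 1)] = counts.get((line[k], m - k + 1), 0) + 1
            k = m + 1
    return counts


def oracle_glrm_features(counts, n_pixels):
    n_runs = sum(counts.values())
    long_run = sum(c * ln * ln for (_, ln), c in counts.items()) / n_runs
    return long_run, n_runs / n_pixels


# --- oracle equivalence -----------------------------------------------------

def test_glcm_matches_enumeration_oracle_exactly(rng):
    for trial in range(60):
        size = int(rng.integers(2, 17))
        tile = np.where(rng.random((size, size)) > 0.5, 255, 0).astype(np.uint8)
        d = DIRECTIONS[trial % 8]
        m = glcm(tile, d)
        levels, P = oracle_glcm(tile, d)
        assert np.array_equal(m.levels, levels)
        assert np.allclose(m.P, P, atol=0)
        mean, corr = glcm_features(m)
        omean, ocorr = oracle_glcm_features(levels, P)
        assert mean == pytest.approx(omean, abs=1e-12)
        if np.isnan(ocorr):
            assert np.isnan(corr)
        else:
            assert corr == pytest.approx(ocorr, abs=1e-12)


def test_glcm_on_multilevel_tiles_matches_oracle(rng):
    for trial in range(20):
        tile = rng.integers(0, 5, (12, 12)).astype(np.uint8)
        d = DIRECTIONS[trial % 8]
        m = glcm(tile, d)
        levels, P = oracle_glcm(tile, d)
        assert np.array_equal(m.levels, levels)
        assert np.allclose(m.P, P, atol=0)


def test_glrm_matches_scanning_oracle_exactly(rng):
    for trial in range(60):
        size = int(rng.integers(2, 17))
        tile = np.where(rng.random((size, size)) > 0.5, 255, 0).astype(np.uint8)
        d = DIRECTIONS[trial % 8]
        m = glrm(tile, d)
        counts = oracle_runs(tile, d)
        # rebuild dict from matrix
        got = {}
        for li, lvl in enumerate(m.levels):
            for ln in range(m.R.shape[1]):
                if m.R[li, ln]:
                    got[(int(lvl), ln + 1)] = int(m.R[li, ln])
        assert got == {(int(v), l): c for (v, l), c in counts.items()}
        lre, rp = glrm_features(m)
        olre, orp = oracle_glrm_features(counts, tile.size)
        assert lre == pytest.approx(olre, abs=1e-12)
        assert rp == pytest.approx(orp, abs=1e-12)


def test_glcm_cross_check_against_skimage(rng):
    """Independent library cross-check of the co-occurrence construction."""
    from skimage.feature import graycomatrix

    tile = rng.integers(0, 4, (20, 20)).astype(np.uint8)
    # skimage angle 0 with distance 1 is displacement (0, +1)
    m = glcm(tile, (0, 1))
    sk = graycomatrix(tile, [1], [0], levels=4, normed=True)[:, :, 0, 0]
    present = np.unique(tile)
    assert np.allclose(m.P, sk[np.ix_(present, present)])


# --- closed-form cases ------------------------------------------------------

class TestClosedForms:
    def test_constant_tile_glcm(self):
        tile = np.full((5, 5), 7, dtype=np.uint8)
        m = glcm(tile, (0, 1))
        assert m.P.shape == (1, 1) and m.P[0, 0] == 1.0
        mean, corr = glcm_features(m)
        assert mean == 7.0
        assert np.isnan(corr)

    def test_single_pair_tile(self):
        tile = np.array([[0, 255]], dtype=np.uint8)
        m = glcm(tile, (0, 1))
        assert m.P[0, 1] == 1.0 and m.P.sum() == 1.0

    def test_constant_row_glrm(self):
        tile = np.array([[5, 5, 5, 5]], dtype=np.uint8)
        lre, rp = glrm_features(glrm(tile, (0, 1)))
        assert lre == 16.0
        assert rp == 0.25

    def test_checkerboard_glrm(self):
        tile = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        lre, rp = glrm_features(glrm(tile, (0, 1)))
        assert lre == 1.0
        assert rp == 1.0

    def test_tile_too_small_for_displacement(self):
        with pytest.raises(ValidationError):
            glcm(np.array([[1]], dtype=np.uint8), (0, 1))


# --- conservation and structural invariants ---------------------------------

def test_glcm_probabilities_and_glrm_pixels_conserved(rng):
    tile = np.where(rng.random((24, 24)) > 0.7, 255, 0).astype(np.uint8)
    for d in DIRECTIONS:
        assert glcm(tile, d).P.sum() == pytest.approx(1.0, abs=1e-12)
        m = glrm(tile, d)
        lengths = np.arange(1, m.R.shape[1] + 1)
        assert (m.R * lengths).sum() == m.n_pixels


def test_run_ratio_one_iff_maximally_alternating():
    checker = np.indices((8, 8)).sum(axis=0) % 2 * 255
    m = glrm(checker.astype(np.uint8), (0, 1))
    assert glrm_features(m)[1] == 1.0
    m_diag = glrm(checker.astype(np.uint8), (1, 1))
    assert glrm_features(m_diag)[1] < 1.0  # diagonals are constant runs


def test_profile_invariant_under_quarter_rotation(small_scene):
    mask = small_scene.truth_mask.pixels
    feats = tile_texture_features(mask)
    feats_rot = tile_texture_features(np.rot90(mask))
    for key, val in feats.items():
        assert feats_rot[key] == pytest.approx(val, abs=1e-9), key


def test_denser_planting_raises_glcm_mean():
    base = dict(width_px=512, height_px=512, in_row_spacing_cm=20.0,
                missing_rate=0.0, touch_rate=0.0, weed_rate=0.0)
    m45 = generate_field(FieldSpec(row_spacing_cm=45.0, **base), 1).truth_mask
    m90 = generate_field(FieldSpec(row_spacing_cm=90.0, **base), 1).truth_mask
    grid = TileGrid(256, 256)
    p45 = texture_profile(m45, grid)
    p90 = texture_profile(m90, grid)
    assert p45["glcm_mean"].mean() > p90["glcm_mean"].mean()


def test_monotone_density_raises_glcm_mean():
    means = []
    for spacing in (90.0, 60.0, 45.0, 30.0):
        mask = generate_field(
            FieldSpec(width_px=384, height_px=384, row_spacing_cm=spacing,
                      in_row_spacing_cm=20.0, missing_rate=0.0, touch_rate=0.0,
                      weed_rate=0.0), 2).truth_mask
        means.append(tile_texture_features(mask.pixels)["glcm_mean"])
    assert means == sorted(means)


def test_touching_plants_inflate_long_run():
    base = dict(width_px=384, height_px=384, row_spacing_cm=45.0,
                in_row_spacing_cm=20.0, missing_rate=0.0, weed_rate=0.0)
    lre = {}
    for touch in (0.0, 0.5):
        mask = generate_field(FieldSpec(touch_rate=touch, **base), 3).truth_mask
        lre[touch] = tile_texture_features(mask.pixels)["glrm_long_run"]
    assert lre[0.5] > lre[0.0]


# --- markup comparison ------------------------------------------------------

class TestCompareMarkups:
    def _profile(self, seed=0):
        mask = generate_field(
            FieldSpec(width_px=512, height_px=512, row_spacing_cm=45.0,
                      in_row_spacing_cm=20.0), seed).truth_mask
        return texture_profile(mask, TileGrid(128, 128))

    def test_self_comparison_is_identity(self):
        prof = self._profile()
        cmp = compare_markups(prof, prof)
        for _, row in cmp.iterrows():
            assert row["mean_diff"] == 0.0
            assert row["slope"] == pytest.approx(1.0, abs=1e-12)
            assert row["intercept"] == pytest.approx(0.0, abs=1e-12)
            assert row["pearson_r"] == pytest.approx(1.0, abs=1e-12)

    def test_affine_shift_detected(self):
        prof = self._profile()
        shifted = prof.copy()
        shifted["glcm_mean"] = shifted["glcm_mean"] + 3.0
        cmp = compare_markups(prof, shifted).set_index("feature")
        row = cmp.loc["glcm_mean"]
        assert row["mean_diff"] == pytest.approx(3.0, abs=1e-9)
        assert row["slope"] == pytest.approx(1.0, abs=1e-9)
        assert row["intercept"] == pytest.approx(3.0, abs=1e-9)
        assert row["paired_test_p"] < 1e-6

    def test_too_few_tiles_rejected(self):
        prof = self._profile().iloc[:2]
        with pytest.raises(ValidationError):
            compare_markups(prof, prof)

    def test_undefined_tiles_dropped_pairwise(self):
        prof = self._profile()
        broken = prof.copy()
        broken.loc[broken.index[0], "glcm_correlation"] = np.nan
        cmp = compare_markups(prof, broken).set_index("feature")
        assert cmp.loc["glcm_correlation", "n_dropped"] == 1
        assert cmp.loc["glcm_mean", "n_dropped"] == 0
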