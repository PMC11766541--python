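"""Synthetic seedling-stage row-crop scenes with exhaustive ground truth.

The generator emulates the geometry of early-season row crops seen from a UAV
at the working scale of 1 px = 1 cm: parallel rows at a configurable spacing
(sugar-beet-like 45 cm vs potato/sunflower-like 90 cm), quasi-regular in-row
plant placement, disc-like green canopies over textured brown soil, missing
plants, touching plant pairs (the merged-contour failure mode of counting),
and off-row weed distractors.  Every scene carries its exact list of plant
centers and the binary truth mask rendered from them, so all downstream
stages are testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .errors import ValidationError
from .field_data import PlantAnnotation, RasterMask, TileGrid, rasterize_centers, tile_image

MASK_RADIUS_CM = 4.0  # radius of the disc painted at each plant center


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and nuisance parameters of a synthetic field scene.

    Spacings and radii are in cm (= px at the working scale).  ``touch_rate``
    is the fraction of plants duplicated at a sub-diameter offset, producing
    pairs whose mask discs merge into one contour.  ``weed_rate`` is the
    expected number of off-row distractor blobs per 100 m^2 (10 m x 10 m).
    """

    width_px: int = 512
    height_px: int = 512
    row_spacing_cm: float = 90.0
    in_row_spacing_cm: float = 25.0
    plant_radius_cm: float = 5.0
    plant_radius_jitter: float = 0.2
    missing_rate: float = 0.0
    #: fraction of in-row neighbour pairs pulled to sub-diameter distance so
    #: their mask discs merge into one elongated contour (plant count is
    #: conserved; only the spacing collapses)
    touch_rate: float = 0.0
    soil_noise: float = 0.3
    weed_rate: float = 0.0
    row_angle_deg: float = 0.0

    def validate(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValidationError("width_px/height_px: must be >= 64")
        for name in ("row_spacing_cm", "in_row_spacing_cm", "plant_radius_cm"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name}: must be positive")
        for name in ("missing_rate", "touch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: must be in [0, 1]")
        if not 0.0 <= self.soil_noise <= 1.0:
            raise ValidationError("soil_noise: must be in [0, 1]")
        if self.weed_rate < 0:
            raise ValidationError("weed_rate: must be >= 0")
        if self.plant_radius_jitter < 0:
            raise ValidationError("plant_radius_jitter: must be >= 0")


@dataclass(frozen=True)
class AnnotationDegradeSpec:
    """Markup-degradation knobs emulating uncorrected, box-derived annotation.

    ``center_jitter_cm`` is the std of an isotropic Gaussian displacement,
    ``drop_rate`` the probability of losing a plant, ``spurious_rate`` the
    expected number of false centers per 100 m^2, and ``box_mode`` re-derives
    each center from an integer-cm bounding box (midpoint quantization).
    """

    center_jitter_cm: float = 0.0
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    box_mode: bool = False

    def validate(self) -> None:
        if self.center_jitter_cm < 0:
            raise ValidationError("center_jitter_cm: must be >= 0")
        if not 0.0 <= self.drop_rate <= 1.0:
            raise ValidationError("drop_rate: must be in [0, 1]")
        if self.spurious_rate < 0:
            raise ValidationError("spurious_rate: must be >= 0")


@dataclass
class FieldScene:
    """A rendered scene plus its exhaustive ground truth."""

    image: np.ndarray  # HxWx3 uint8
    centers: list[tuple[float, float]]
    truth_mask: RasterMask
    spec: FieldSpec
    seed: int

    def annotation(self) -> PlantAnnotation:
        return PlantAnnotation(list(self.centers), source="synthetic")


def _soil_background(h: int, w: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Brown soil: low-frequency luminance field plus per-pixel speckle."""
    base = np.array([118.0, 92.0, 66.0])  # dry-loam RGB
    coarse = rng.standard_normal((max(h // 32, 2), max(w // 32, 2)))
    coarse = zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)[:h, :w]
    coarse = gaussian_filter(coarse, 3.0)
    coarse /= max(np.abs(coarse).max(), 1e-9)
    speckle = rng.standard_normal((h, w)) * 0.25
    lum = 1.0 + amplitude * (0.8 * coarse + speckle)
    img = base[None, None, :] * lum[:, :, None]
    # mild independent channel noise keeps color non-flat
    img += rng.standard_normal((h, w, 3)) * 255 * 0.02 * amplitude
    return img


def _paint_plant(img: np.ndarray, x: float, y: float, radius: float,
                 rng: np.random.Generator) -> None:
    """Radial green blob with a soft edge and multiplicative brightness noise."""
    h, w = img.shape[:2]
    r_out = radius * 1.15
    j0, j1 = max(int(x - r_out - 1), 0), min(int(x + r_out + 2), w)
    i0, i1 = max(int(y - r_out - 1), 0), min(int(y + r_out + 2), h)
    if j0 >= j1 or i0 >= i1:
        return
    jj, ii = np.meshgrid(np.arange(j0, j1) + 0.5, np.arange(i0, i1) + 0.5)
    d = np.sqrt((jj - x) ** 2 + (ii - y) ** 2) / radius
    alpha = np.clip(1.15 - d, 0.0, 1.0) ** 0.7  # soft edge
    alpha = np.clip(alpha, 0.0, 1.0)
    brightness = 1.0 + 0.25 * rng.standard_normal()
    green = np.array([62.0, 148.0, 60.0]) * brightness
    patch = img[i0:i1, j0:j1]
    patch[...] = patch * (1 - alpha[:, :, None]) + green[None, None, :] * alpha[:, :, None]


def _row_layout(spec: FieldSpec, rng: np.random.Generator) -> list[list[tuple[float, float]]]:
    """Place plants on parallel rows; returns per-row lists of centers in cm."""
    w, h = float(spec.width_px), float(spec.height_px)
    s, d = spec.row_spacing_cm, spec.in_row_spacing_cm
    theta = np.deg2rad(spec.row_angle_deg)
    u = np.array([np.cos(theta), np.sin(theta)])   # along-row direction
    v = np.array([-np.sin(theta), np.cos(theta)])  # across-row direction
    # lattice: rows at (k + 1/2) * s along v, slots at (m + 1/2) * d along u,
    # covering the projections of the image corners
    corners = np.array([[0.0, 0.0], [w, 0.0], [0.0, h], [w, h]])
    a, b = corners @ u, corners @ v
    rows: list[list[tuple[float, float]]] = []
    for k in range(int(np.floor(b.min() / s)) - 1, int(np.ceil(b.max() / s)) + 1):
        # each row has its own sowing phase, so slots do not align across rows
        phase = rng.uniform(-0.5, 0.5) * d
        row: list[tuple[float, float]] = []
        for m in range(int(np.floor(a.min() / d)) - 1, int(np.ceil(a.max() / d)) + 1):
            pos = u * ((m + 0.5) * d + phase) + v * ((k + 0.5) * s)
            # quasi-regular sowing: in-row jitter plus slight row wobble
            pos = pos + u * rng.uniform(-0.15, 0.15) * d + v * rng.normal(0.0, 0.03 * s)
            x, y = float(pos[0]), float(pos[1])
            if 1.0 <= x < w - 1.0 and 1.0 <= y < h - 1.0:
                row.append((x, y))
        if row:
            rows.append(row)
    return rows


def generate_field(spec: FieldSpec, seed: int) -> FieldScene:
    """Render one synthetic scene; deterministic for fixed ``(spec, seed)``."""
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    img = _soil_background(h, w, spec.soil_noise, rng)

    rows = _row_layout(spec, rng)
    survived = [[p for p in row if rng.random() >= spec.missing_rate] for row in rows]
    # touching pairs: pull an in-row neighbour to sub-diameter distance so the
    # rasterized discs merge into one elongated contour (count conserved)
    r = spec.plant_radius_cm
    for row in survived:
        i = 0
        while i < len(row) - 1:
            if spec.touch_rate > 0 and rng.random() < spec.touch_rate:
                p0 = np.asarray(row[i])
                p1 = np.asarray(row[i + 1])
                vec = p1 - p0
                norm = float(np.linalg.norm(vec))
                if norm > 0:
                    dist = rng.uniform(0.8 * r, 1.6 * r)
                    moved = p0 + vec / norm * dist
                    if 1.0 <= moved[0] < w - 1.0 and 1.0 <= moved[1] < h - 1.0:
                        row[i + 1] = (float(moved[0]), float(moved[1]))
                i += 2  # a plant joins at most one touching pair
            else:
                i += 1
    kept = [p for row in survived for p in row]

    # weeds: generic off-row distractor blobs, not in the ground truth
    area_100m2 = (h * w) / 1e6  # cm^2 -> units of 100 m^2
    n_weeds = rng.poisson(spec.weed_rate * area_100m2)
    for _ in range(n_weeds):
        wx, wy = rng.uniform(2, w - 2), rng.uniform(2, h - 2)
        wr = rng.uniform(0.3, 0.7) * spec.plant_radius_cm
        _paint_plant(img, wx, wy, wr, rng)

    for x, y in kept:
        radius = spec.plant_radius_cm * (
            1.0 + rng.uniform(-spec.plant_radius_jitter, spec.plant_radius_jitter)
        )
        _paint_plant(img, x, y, radius, rng)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = rasterize_centers(kept, (h, w), radius_cm=MASK_RADIUS_CM)
    return FieldScene(image=image, centers=kept, truth_mask=truth, spec=spec, seed=seed)


def degrade_annotations(
    scene: FieldScene, dspec: AnnotationDegradeSpec, seed: int
) -> PlantAnnotation:
    """Produce a lower-quality markup of a scene (drops, jitter, spurious points)."""
    dspec.validate()
    rng = np.random.default_rng(seed)
    h, w = scene.truth_mask.shape
    out: list[tuple[float, float]] = []
    for x, y in scene.centers:
        if rng.random() < dspec.drop_rate:
            continue
        if dspec.center_jitter_cm > 0:
            x = x + rng.normal(0.0, dspec.center_jitter_cm)
            y = y + rng.normal(0.0, dspec.center_jitter_cm)
        out.append((float(np.clip(x, 0, w - 1e-6)), float(np.clip(y, 0, h - 1e-6))))
    area_100m2 = (h * w) / 1e6
    for _ in range(rng.poisson(dspec.spurious_rate * area_100m2)):
        out.append((float(rng.uniform(0, w)), float(rng.uniform(0, h))))
    if dspec.box_mode:
        # inflate to integer-cm boxes and re-derive midpoints (quantization)
        r = scene.spec.plant_radius_cm
        boxes = [
            (np.floor(x - r), np.floor(y - r), np.ceil(x + r), np.ceil(y + r))
            for x, y in out
        ]
        out = [((b[0] + b[2]) / 2.0, (b[1] + b[3]) / 2.0) for b in boxes]
        return PlantAnnotation(out, source="box_derived",
                               boxes=[tuple(map(float, b)) for b in boxes])
    src = "synthetic" if (dspec.center_jitter_cm == 0 and dspec.drop_rate == 0
                          and dspec.spurious_rate == 0) else "manual_point"
    return PlantAnnotation(out, source=src)


@dataclass
class SegDataset:
    """Co-registered (image tile, mask tile) pairs with a scene-disjoint split."""

    images: np.ndarray  # (N, tile, tile, 3) uint8
    masks: np.ndarray   # (N, tile, tile) uint8 {0, 255}
    split: np.ndarray   # (N,) strings in {train, val, test}
    scene_id: np.ndarray  # (N,) int

    def subset(self, which: str) -> "SegDataset":
        sel = self.split == which
        return SegDataset(self.images[sel], self.masks[sel], self.split[sel],
                          self.scene_id[sel])

    def __len__(self) -> int:
        return len(self.images)


def generate_dataset(
    specs: Sequence[FieldSpec],
    n_per_spec: int,
    tile_px: int,
    seed: int,
    degrade: AnnotationDegradeSpec | None = None,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> SegDataset:
    """Generate scenes per spec and cut them into co-registered training tiles.

    Splits are disjoint by scene (no tile of one scene crosses splits).  When
    ``degrade`` is given, training masks are rasterized from the degraded
    annotation instead of the truth — the low-quality-markup training regime.
    """
    for spec in specs:
        spec.validate()
        if tile_px > min(spec.width_px, spec.height_px):
            raise ValidationError(
                f"tile_px {tile_px} exceeds scene dimension "
                f"{min(spec.width_px, spec.height_px)}"
            )
    ss = np.random.SeedSequence(seed)
    scene_seeds = [int(s) for s in ss.generate_state(len(specs) * n_per_spec)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    grid = TileGrid(tile_px, tile_px, "drop_partial")

    images, masks, splits, scene_ids = [], [], [], []
    sid = 0
    for spec in specs:
        for k in range(n_per_spec):
            scene_seed = scene_seeds[sid] % (2**31)
            scene = generate_field(spec, scene_seed)
            if degrade is not None:
                ann = degrade_annotations(scene, degrade, scene_seed + 1)
                mask = rasterize_centers(ann, scene.truth_mask.shape, MASK_RADIUS_CM)
            else:
                mask = scene.truth_mask
            u = rng.random()
            if u < split_fractions[0]:
                part = "train"
            elif u < split_fractions[0] + split_fractions[1]:
                part = "val"
            else:
                part = "test"
            img_tiles = tile_image(scene.image, grid)
            mask_tiles = tile_image(mask, grid)
            for (off, t_img), (_, t_mask) in zip(img_tiles, mask_tiles):
                images.append(t_img)
                masks.append(t_mask)
                splits.append(part)
                scene_ids.append(sid)
            sid += 1
    return SegDataset(
        np.stack(images), np.stack(masks),
        np.array(splits), np.array(scene_ids),
    )
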