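"""Encoder-decoder semantic segmentation of plant-center discs.

The model is a U-Net: a residual-network encoder (basic-block 18/34-layer or
bottleneck 50-layer profile) that downsamples the input 32x, and a decoder
that upsamples back with skip concatenations from every encoder resolution.
The output is a single-channel plant-probability map the size of the input.
Training minimizes the DiceCE loss — binary cross-entropy plus one minus the
Dice similarity — with the Adam optimizer and a learning rate decaying
linearly over epochs; the best model is the epoch with the highest
validation IoU.

``width_multiplier`` and ``input_tile_px`` are desk-scale knobs: at
(1.0, 512) the architecture matches the full-size network (the 18-layer
encoder bottleneck is then 512 channels at 16 x 16), while small multipliers
give a network trainable on a CPU in minutes.
"""

from __future__ import annotations

import copy
import csv
import logging
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import rescale, rotate

from . import nn
from .errors import ValidationError
from .field_data import Orthomosaic, RasterMask
from .synthetic_fields import SegDataset

log = logging.getLogger(__name__)

#: residual-stage block counts per encoder profile
ENCODER_PROFILES = {
    "rn18": ("basic", [2, 2, 2, 2]),
    "rn34": ("basic", [3, 4, 6, 3]),
    "rn50": ("bottleneck", [3, 4, 6, 3]),
}


@dataclass(frozen=True)
class SegModelConfig:
    encoder: str = "rn18"
    width_multiplier: float = 1.0
    input_tile_px: int = 512

    def validate(self) -> None:
        if self.encoder not in ENCODER_PROFILES:
            raise ValidationError(
                f"encoder: {self.encoder!r} not in {sorted(ENCODER_PROFILES)}"
            )
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValidationError("width_multiplier: must be in (0, 1]")
        if self.input_tile_px % 32 != 0:
            raise ValidationError("input_tile_px: must be divisible by 32")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    lr_start: float = 1e-4
    lr_end: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs: must be >= 1")
        if not self.lr_start > self.lr_end > 0:
            raise ValidationError("learning rates: need lr_start > lr_end > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size: must be >= 1")


@dataclass(frozen=True)
class AugConfig:
    rotate_deg_max: float = 90.0
    scale_jitter_max: float = 0.3
    brightness_contrast: bool = True
    gamma_jitter: bool = True
    hflip: bool = True
    vflip: bool = True
    crop_px: int = 512

    def validate(self) -> None:
        if self.rotate_deg_max < 0 or self.scale_jitter_max < 0:
            raise ValidationError("augmentation magnitudes must be >= 0")
        if self.crop_px < 1:
            raise ValidationError("crop_px: must be >= 1")


# ---------------------------------------------------------------------------
# model blocks


def _ch(base: int, width: float) -> int:
    return max(1, int(round(base * width)))


class _BasicBlock(nn.Layer):
    def __init__(self, c_in: int, c_out: int, stride: int, rng):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(c_out, c_out, 3, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down: nn.Sequential | None = nn.Sequential(
                nn.Conv2d(c_in, c_out, 1, stride, pad=0, bias=False, rng=rng),
                nn.BatchNorm2d(c_out),
            )
        else:
            self.down = None
        self.relu_out = nn.ReLU()

    def params(self):
        ps = (self.conv1.params() + self.bn1.params() + self.conv2.params()
              + self.bn2.params())
        if self.down is not None:
            ps += self.down.params()
        return ps

    def forward(self, x, train):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        sc = x if self.down is None else self.down.forward(x, train)
        return self.relu_out.forward(y + sc, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.bn1.backward(self.relu1.backward(dmain))
        dx = self.conv1.backward(dmain)
        dx += d if self.down is None else self.down.backward(d)
        return dx


class _Bottleneck(nn.Layer):
    expansion = 4

    def __init__(self, c_in: int, planes: int, stride: int, rng):
        c_out = planes * self.expansion
        self.conv1 = nn.Conv2d(c_in, planes, 1, 1, pad=0, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(planes)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(planes, planes, 3, stride, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(planes)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv2d(planes, c_out, 1, 1, pad=0, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down: nn.Sequential | None = nn.Sequential(
                nn.Conv2d(c_in, c_out, 1, stride, pad=0, bias=False, rng=rng),
                nn.BatchNorm2d(c_out),
            )
        else:
            self.down = None
        self.relu_out = nn.ReLU()

    def params(self):
        ps = (self.conv1.params() + self.bn1.params() + self.conv2.params()
              + self.bn2.params() + self.conv3.params() + self.bn3.params())
        if self.down is not None:
            ps += self.down.params()
        return ps

    def forward(self, x, train):
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.relu2.forward(self.bn2.forward(self.conv2.forward(y, train), train), train)
        y = self.bn3.forward(self.conv3.forward(y, train), train)
        sc = x if self.down is None else self.down.forward(x, train)
        return self.relu_out.forward(y + sc, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dm = self.conv3.backward(self.bn3.backward(d))
        dm = self.conv2.backward(self.bn2.backward(self.relu2.backward(dm)))
        dm = self.conv1.backward(self.bn1.backward(self.relu1.backward(dm)))
        dm += d if self.down is None else self.down.backward(d)
        return dm


class _DecoderBlock(nn.Layer):
    """Upsample x2, concatenate the skip, then two conv-BN-ReLU stages."""

    def __init__(self, c_in: int, c_skip: int, c_out: int, rng):
        self.up = nn.Upsample2x()
        self.c_skip = c_skip
        self.block = nn.Sequential(
            nn.Conv2d(c_in + c_skip, c_out, 3, 1, bias=False, rng=rng),
            nn.BatchNorm2d(c_out),
            nn.ReLU(),
            nn.Conv2d(c_out, c_out, 3, 1, bias=False, rng=rng),
            nn.BatchNorm2d(c_out),
            nn.ReLU(),
        )

    def params(self):
        return self.block.params()

    def forward(self, x, skip, train):
        x = self.up.forward(x, train)
        if skip is not None:
            x = np.concatenate([x, skip], axis=1)
        return self.block.forward(x, train)

    def backward(self, dy):
        d = self.block.backward(dy)
        if self.c_skip:
            d, dskip = d[:, : -self.c_skip], d[:, -self.c_skip :]
        else:
            dskip = None
        return self.up.backward(d), dskip


class SegModel:
    """U-Net with a residual encoder; maps (N,H,W,3) uint8 to probabilities."""

    def __init__(self, config: SegModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        kind, blocks = ENCODER_PROFILES[config.encoder]
        w = config.width_multiplier
        base = _ch(64, w)

        self.stem_conv = nn.Conv2d(3, base, 7, 2, pad=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(base)
        self.stem_relu = nn.ReLU()
        self.pool = nn.MaxPool2d(3, 2, 1)

        self.stages: list[list[nn.Layer]] = []
        stage_out: list[int] = []
        c_in = base
        for i, n_blocks in enumerate(blocks):
            planes = _ch(64 * (2**i), w)
            stage: list[nn.Layer] = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and i > 0) else 1
                if kind == "basic":
                    stage.append(_BasicBlock(c_in, planes, stride, rng))
                    c_in = planes
                else:
                    stage.append(_Bottleneck(c_in, planes, stride, rng))
                    c_in = planes * _Bottleneck.expansion
            self.stages.append(stage)
            stage_out.append(c_in)

        # decoder: deepest feature up through the skips, final stage skip-free
        dec_ch = [_ch(c, w) for c in (256, 128, 64, 32, 16)]
        skips = [stage_out[2], stage_out[1], stage_out[0], base, 0]
        self.decoder: list[_DecoderBlock] = []
        c = stage_out[3]
        for c_out, c_skip in zip(dec_ch, skips):
            self.decoder.append(_DecoderBlock(c, c_skip, c_out, rng))
            c = c_out
        self.head = nn.Conv2d(c, 1, 3, 1, rng=rng)
        self._cache = None

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = self.stem_conv.params() + self.stem_bn.params()
        for stage in self.stages:
            for block in stage:
                ps += block.params()
        for dec in self.decoder:
            ps += dec.params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward/backward --------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        """``x``: (N, H, W, 3) uint8 or float; returns (N, H, W) logits."""
        x = np.ascontiguousarray(
            x.astype(np.float32).transpose(0, 3, 1, 2) / 255.0 - 0.5
        )
        f0 = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, train), train), train
        )
        h = self.pool.forward(f0, train)
        feats = []
        for stage in self.stages:
            for block in stage:
                h = block.forward(h, train)
            feats.append(h)
        skips = [feats[2], feats[1], feats[0], f0, None]
        h = feats[3]
        for dec, skip in zip(self.decoder, skips):
            h = dec.forward(h, skip, train)
        logits = self.head.forward(h, train)
        return logits[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None])
        dskips = []
        for dec in reversed(self.decoder):
            d, dskip = dec.backward(d)
            dskips.append(dskip)
        dskips.reverse()  # grads for [feats[2], feats[1], feats[0], f0, None]
        dstage = [dskips[2], dskips[1], dskips[0], d]  # per encoder stage
        g = dstage[3]
        for i in (3, 2, 1, 0):
            for block in reversed(self.stages[i]):
                g = block.backward(g)
            if i > 0 and dstage[i - 1] is not None:
                g = g + dstage[i - 1]
        g = self.pool.backward(g)
        if dskips[3] is not None:
            g = g + dskips[3]
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probabilities for a batch of (N, H, W, 3) tiles in eval mode."""
        return _sigmoid(self.forward_logits(x, train=False))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = [p.value for p in self.params()]
        bn_stats = []
        for layer in _iter_batchnorms(self):
            bn_stats.append((layer.running_mean.copy(), layer.running_var.copy()))
        with open(path, "wb") as fh:
            pickle.dump({"config": asdict(self.config), "params": state,
                         "bn": bn_stats}, fh)
        sidecar = path.with_suffix(path.suffix + ".json")
        import json

        with open(sidecar, "w") as fh:
            json.dump({"model": asdict(self.config)}, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(SegModelConfig(**blob["config"]))
        for p, v in zip(model.params(), blob["params"]):
            p.value[...] = v
        for layer, (rm, rv) in zip(_iter_batchnorms(model), blob["bn"]):
            layer.running_mean[...] = rm
            layer.running_var[...] = rv
        return model


def _iter_batchnorms(model: SegModel):
    def walk(obj):
        if isinstance(obj, nn.BatchNorm2d):
            yield obj
        elif isinstance(obj, nn.Sequential):
            for l in obj.layers:
                yield from walk(l)
        elif isinstance(obj, (_BasicBlock, _Bottleneck)):
            for name in ("bn1", "bn2", "bn3", "down"):
                sub = getattr(obj, name, None)
                if sub is not None:
                    yield from walk(sub)
        elif isinstance(obj, _DecoderBlock):
            yield from walk(obj.block)

    yield from walk(model.stem_bn)
    for stage in model.stages:
        for block in stage:
            yield from walk(block)
    for dec in model.decoder:
        yield from walk(dec)


def build_model(config: SegModelConfig, seed: int = 0) -> SegModel:
    """Construct the segmentation network for a given encoder profile."""
    return SegModel(config, seed=seed)


# ---------------------------------------------------------------------------
# loss


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dice_ce_loss(
    pred: np.ndarray, target: np.ndarray, eps: float = 1.0, clamp: float = 1e-7
) -> float:
    """DiceCE on a probability map: BCE(pred, target) + (1 - Dice similarity).

    ``Dice = (2 sum(p t) + eps) / (sum p + sum t + eps)`` with smoothing
    ``eps`` = 1.  The target must be two-valued ({0,1} or {0,255}); pred is
    clamped away from 0/1 before the log.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {target.shape}")
    vals = np.unique(target)
    if not set(vals).issubset({0.0, 1.0, 255.0}):
        raise ValidationError("target: must be binary")
    t = (target > 0).astype(np.float64)
    p = np.clip(pred, clamp, 1.0 - clamp)
    ce = float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))
    dice = (2.0 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps)
    return ce + (1.0 - float(dice))


def _dice_ce_with_grad(logits: np.ndarray, target01: np.ndarray, eps: float = 1.0):
    """Loss and d(loss)/d(logits) for training; target01 is float {0,1}."""
    p = _sigmoid(logits.astype(np.float64))
    n = p.size
    t = target01
    # stable BCE-with-logits
    z = logits.astype(np.float64)
    ce = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    sp, st, spt = p.sum(), t.sum(), (p * t).sum()
    dice = (2.0 * spt + eps) / (sp + st + eps)
    loss = ce + (1.0 - dice)
    # gradients wrt p, chain through sigmoid for the dice term
    dce_dz = (p - t) / n
    ddice_dp = (2.0 * t * (sp + st + eps) - (2.0 * spt + eps)) / (sp + st + eps) ** 2
    ddice_dz = ddice_dp * p * (1.0 - p)
    grad = (dce_dz - ddice_dz).astype(np.float32)
    return loss, grad


# ---------------------------------------------------------------------------
# augmentation


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugConfig,
    seed: int | np.random.Generator,
    force: set[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random co-registered augmentation of an (image, mask) pair.

    Geometric transforms (rotation, scale jitter, flips, crop) hit both
    arrays — nearest-neighbour for the mask so it stays two-valued — while
    photometric transforms (brightness/contrast, gamma) touch the image only.
    ``force`` can name ops ("hflip", "vflip", "rotate90") to apply
    unconditionally (rotate90 pins the rotation angle to exactly 90 degrees).
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    force = force or set()
    img = np.asarray(image)
    msk = np.asarray(mask)
    if img.shape[:2] != msk.shape[:2]:
        raise ValidationError("image and mask must be co-registered")

    if config.rotate_deg_max > 0:
        if "rotate90" in force:
            angle = 90.0
        else:
            angle = float(rng.uniform(0.0, config.rotate_deg_max))
        img = rotate(img, angle, resize=False, order=1, mode="reflect",
                     preserve_range=True)
        msk = rotate(msk, angle, resize=False, order=0, mode="reflect",
                     preserve_range=True)
    if config.scale_jitter_max > 0:
        s = float(1.0 + rng.uniform(-config.scale_jitter_max, config.scale_jitter_max))
        h0, w0 = img.shape[:2]
        img = rescale(img, s, order=1, mode="reflect", preserve_range=True,
                      channel_axis=-1 if img.ndim == 3 else None, anti_aliasing=s < 1)
        msk = rescale(msk, s, order=0, mode="reflect", preserve_range=True,
                      anti_aliasing=False)
        img = _fit_to(img, h0, w0)
        msk = _fit_to(msk, h0, w0)
    if config.hflip and ("hflip" in force or rng.random() < 0.5):
        img, msk = img[:, ::-1], msk[:, ::-1]
    if config.vflip and ("vflip" in force or rng.random() < 0.5):
        img, msk = img[::-1], msk[::-1]
    if config.brightness_contrast:
        alpha = float(1.0 + rng.uniform(-0.2, 0.2))
        beta = float(rng.uniform(-20.0, 20.0))
        img = np.clip(img.astype(np.float64) * alpha + beta, 0, 255)
    if config.gamma_jitter:
        gamma = float(rng.uniform(0.8, 1.25))
        img = 255.0 * (np.clip(img, 0, 255) / 255.0) ** gamma
    h, w = img.shape[:2]
    if config.crop_px < min(h, w):
        r0 = int(rng.integers(0, h - config.crop_px + 1))
        c0 = int(rng.integers(0, w - config.crop_px + 1))
        img = img[r0 : r0 + config.crop_px, c0 : c0 + config.crop_px]
        msk = msk[r0 : r0 + config.crop_px, c0 : c0 + config.crop_px]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    msk = np.where(np.asarray(msk) > 127, 255, 0).astype(np.uint8)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def _fit_to(arr: np.ndarray, h: int, w: int) -> np.ndarray:
    """Center-crop or reflect-pad to (h, w)."""
    ah, aw = arr.shape[:2]
    if ah > h:
        top = (ah - h) // 2
        arr = arr[top : top + h]
    if aw > w:
        left = (aw - w) // 2
        arr = arr[:, left : left + w]
    ah, aw = arr.shape[:2]
    if ah < h or aw < w:
        pad = [((h - ah) // 2, h - ah - (h - ah) // 2),
               ((w - aw) // 2, w - aw - (w - aw) // 2)]
        pad += [(0, 0)] * (arr.ndim - 2)
        arr = np.pad(arr, pad, mode="reflect")
    return arr


# ---------------------------------------------------------------------------
# training


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float
    train_iou: float
    val_iou: float


def _batch_iou(prob: np.ndarray, target01: np.ndarray, threshold: float = 0.5):
    pred = prob >= threshold
    t = target01 > 0
    inter = np.logical_and(pred, t).sum()
    union = np.logical_or(pred, t).sum()
    return inter, union


def train(
    model: SegModel,
    train_set: SegDataset,
    val_set: SegDataset,
    tconfig: TrainConfig,
    aug: AugConfig | None = None,
) -> tuple[SegModel, list[EpochRecord]]:
    """Fit the model; returns (best model by validation IoU, epoch history).

    The learning rate at epoch e is ``lr_start + (lr_end - lr_start) * e /
    (epochs - 1)`` (constant ``lr_start`` for a single epoch).  Augmentation,
    when given, is applied on the fly to training tiles only.
    """
    tconfig.validate()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValidationError("train/val datasets must be non-empty")
    rng = np.random.default_rng(tconfig.seed)
    opt = nn.Adam(model.params(), lr=tconfig.lr_start)
    history: list[EpochRecord] = []
    best_iou, best_state = -1.0, None
    n = len(train_set)
    for epoch in range(tconfig.epochs):
        if tconfig.epochs == 1:
            lr = tconfig.lr_start
        else:
            lr = tconfig.lr_start + (tconfig.lr_end - tconfig.lr_start) * epoch / (
                tconfig.epochs - 1
            )
        opt.lr = lr
        order = rng.permutation(n)
        tot_loss, n_batches = 0.0, 0
        inter_sum, union_sum = 0, 0
        for b0 in range(0, n, tconfig.batch_size):
            idx = order[b0 : b0 + tconfig.batch_size]
            imgs = train_set.images[idx]
            msks = train_set.masks[idx]
            if aug is not None:
                pairs = [augment(im, mk, aug, rng) for im, mk in zip(imgs, msks)]
                imgs = np.stack([p[0] for p in pairs])
                msks = np.stack([p[1] for p in pairs])
            t01 = (msks > 0).astype(np.float64)
            logits = model.forward_logits(imgs, train=True)
            loss, grad = _dice_ce_with_grad(logits, t01)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            tot_loss += loss
            n_batches += 1
            i, u = _batch_iou(_sigmoid(logits), t01)
            inter_sum += i
            union_sum += u
        train_loss = tot_loss / n_batches
        train_iou = inter_sum / union_sum if union_sum else 1.0

        val_loss, val_iou = evaluate_on(model, val_set, tconfig.batch_size)
        history.append(
            EpochRecord(epoch, lr, train_loss, val_loss, float(train_iou), float(val_iou))
        )
        log.info(
            "epoch %d lr %.2e train_loss %.4f val_loss %.4f train_iou %.3f val_iou %.3f",
            epoch, lr, train_loss, val_loss, train_iou, val_iou,
        )
        if val_iou > best_iou:
            best_iou = val_iou
            best_state = (
                [p.value.copy() for p in model.params()],
                [(bn.running_mean.copy(), bn.running_var.copy())
                 for bn in _iter_batchnorms(model)],
            )
    if best_state is not None:
        for p, v in zip(model.params(), best_state[0]):
            p.value[...] = v
        for bn, (rm, rv) in zip(_iter_batchnorms(model), best_state[1]):
            bn.running_mean[...] = rm
            bn.running_var[...] = rv
    return model, history


def evaluate_on(model: SegModel, dataset: SegDataset, batch_size: int = 8):
    """Mean DiceCE loss and pooled IoU of a dataset in eval mode."""
    tot_loss, n_batches = 0.0, 0
    inter_sum, union_sum = 0, 0
    for b0 in range(0, len(dataset), batch_size):
        imgs = dataset.images[b0 : b0 + batch_size]
        msks = dataset.masks[b0 : b0 + batch_size]
        t01 = (msks > 0).astype(np.float64)
        logits = model.forward_logits(imgs, train=False)
        loss, _ = _dice_ce_with_grad(logits, t01)
        tot_loss += loss
        n_batches += 1
        i, u = _batch_iou(_sigmoid(logits), t01)
        inter_sum += i
        union_sum += u
    return tot_loss / max(n_batches, 1), (inter_sum / union_sum if union_sum else 1.0)


def write_history_csv(history: list[EpochRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "lr", "train_loss", "val_loss", "train_iou", "val_iou"])
        for rec in history:
            writer.writerow(
                [rec.epoch, rec.lr, rec.train_loss, rec.val_loss, rec.train_iou, rec.val_iou]
            )


# ---------------------------------------------------------------------------
# tiled inference


def predict_mask(
    model: SegModel,
    image: Orthomosaic | np.ndarray,
    tile_px: int | None = None,
    threshold: float = 0.5,
    overlap: int = 64,
) -> RasterMask:
    """Segment a whole image by sliding tiles; overlaps are mean-blended.

    The image must already be at the working scale (1 px = 1 cm).  Images
    smaller than the tile are reflect-padded, predicted, and cropped back.
    """
    arr = image.pixels if isinstance(image, Orthomosaic) else np.asarray(image)
    tile = tile_px or model.config.input_tile_px
    h, w = arr.shape[:2]
    pad_h, pad_w = max(tile - h, 0), max(tile - w, 0)
    if pad_h or pad_w:
        arr = np.pad(arr, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    ph, pw = arr.shape[:2]
    stride = max(tile - overlap, 1)
    prob_sum = np.zeros((ph, pw), dtype=np.float64)
    weight = np.zeros((ph, pw), dtype=np.float64)
    rows = sorted({min(r, ph - tile) for r in range(0, ph - tile + stride, stride)})
    cols = sorted({min(c, pw - tile) for c in range(0, pw - tile + stride, stride)})
    for r0 in rows:
        for c0 in cols:
            patch = arr[r0 : r0 + tile, c0 : c0 + tile]
            prob = model.predict_proba(patch[None])[0]
            prob_sum[r0 : r0 + tile, c0 : c0 + tile] += prob
            weight[r0 : r0 + tile, c0 : c0 + tile] += 1.0
    prob = prob_sum / weight
    mask = np.where(prob[:h, :w] >= threshold, 255, 0).astype(np.uint8)
    return RasterMask(mask)
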