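"""Pixel-classifier training and prediction.

Builds training data from annotated (image, instance-mask) pairs: cell-cell
borders are derived by dilating each cell and zeroing pixels where two
dilations intersect, so the binary target is 1 on cell bodies and 0 on
background *and* borders; images are robustly normalized, cut into tiles
overlapping by at least half, and augmented (rotation, shear, zoom, flips,
brightness).  The classifier is a small U-Net-style encoder-decoder with
skip connections, a sigmoid pixel output and per-pixel binary cross-entropy,
implemented directly on numpy (im2col convolutions, explicit backward
passes, Adam).  Prediction runs on whole images, padding to the network's
downsampling factor and cropping back.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi
from skimage.transform import AffineTransform, warp

__all__ = [
    "AnnotatedPair",
    "AugmentationConfig",
    "TrainingConfig",
    "ModelHandle",
    "make_pixel_target",
    "tile_pairs",
    "augment_pair",
    "normalize_image",
    "train",
    "predict",
]


@dataclass
class AnnotatedPair:
    """A raw grayscale image with its instance-label ground truth."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


@dataclass(frozen=True)
class AugmentationConfig:
    """Geometric + photometric augmentation ranges (training defaults)."""

    rotation_range_deg: float = 90.0
    shear_range_deg: float = 45.0
    zoom_range: tuple[float, float] = (0.5, 2.0)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    brightness_range: tuple[float, float] = (0.5, 1.5)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.zoom_range[0] <= self.zoom_range[1]:
            raise ValueError("invalid zoom_range")
        if not 0 < self.brightness_range[0] <= self.brightness_range[1]:
            raise ValueError("invalid brightness_range")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        return cls(rotation_range_deg=0.0, shear_range_deg=0.0,
                   zoom_range=(1.0, 1.0), horizontal_flip=False,
                   vertical_flip=False, brightness_range=(1.0, 1.0))


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 25
    epochs: int = 100
    tile_size: int = 256
    depth: int = 2  # number of 2x downsamplings
    base_filters: int = 8
    learning_rate: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.tile_size % (2**self.depth) != 0:
            raise ValueError(
                f"tile_size {self.tile_size} is not a multiple of "
                f"2^depth = {2**self.depth}"
            )


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def make_pixel_target(mask: np.ndarray, dilation_px: int = 1) -> np.ndarray:
    """Binary pixel target: 1 on cell bodies, 0 on background and on the
    borders where the dilations of two distinct cells intersect."""
    if dilation_px < 1:
        raise ValueError("dilation_px must be >= 1")
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    target = (mask > 0).astype(np.uint8)
    if len(labels) < 2:
        return target
    coverage = np.zeros(mask.shape, dtype=np.int16)
    struct = np.ones((3, 3), bool)
    for lab in labels:
        coverage += ndi.binary_dilation(mask == lab, struct,
                                        iterations=dilation_px)
    target[coverage >= 2] = 0
    return target


def _tile_starts(dim: int, tile: int) -> list[int]:
    """Window origins with stride tile/2, last window flush with the edge."""
    stride = tile // 2
    starts = list(range(0, dim - tile, stride))
    starts.append(dim - tile)
    return sorted(set(starts))


def _mirror_pad_to(arr: np.ndarray, size: int) -> np.ndarray:
    pr = max(size - arr.shape[0], 0)
    pc = max(size - arr.shape[1], 0)
    if pr == 0 and pc == 0:
        return arr
    return np.pad(arr, ((0, pr), (0, pc)), mode="reflect")


def tile_pairs(
    image: np.ndarray, target: np.ndarray, tile_size: int = 256
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut an (image, target) pair into tiles overlapping by at least half
    in each dimension; images smaller than the tile are mirror-padded."""
    if image.shape != target.shape:
        raise ValueError("image and target shapes differ")
    image = _mirror_pad_to(np.asarray(image), tile_size)
    target = _mirror_pad_to(np.asarray(target), tile_size)
    out = []
    for r in _tile_starts(image.shape[0], tile_size):
        for c in _tile_starts(image.shape[1], tile_size):
            out.append((
                image[r:r + tile_size, c:c + tile_size].copy(),
                target[r:r + tile_size, c:c + tile_size].copy(),
            ))
    return out


def augment_pair(
    image: np.ndarray,
    target: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random augmentation draw to an (image, target) tile.

    The same geometric transform (rotation, shear, zoom, flips about the
    tile center) is applied to both; the target uses nearest-neighbor
    interpolation so it stays binary, the image bilinear.  The brightness
    multiplier applies to the image only.
    """
    image = np.asarray(image, dtype=float)
    target = np.asarray(target, dtype=float)
    rot = math.radians(rng.uniform(-config.rotation_range_deg,
                                   config.rotation_range_deg))
    shear = math.radians(rng.uniform(-config.shear_range_deg,
                                     config.shear_range_deg))
    zoom = rng.uniform(*config.zoom_range)
    flip_h = config.horizontal_flip and rng.random() < 0.5
    flip_v = config.vertical_flip and rng.random() < 0.5
    brightness = rng.uniform(*config.brightness_range)

    center = np.array([(image.shape[1] - 1) / 2, (image.shape[0] - 1) / 2])
    tf = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=rot, shear=shear, scale=(zoom, zoom))
        + AffineTransform(translation=center)
    )
    needs_warp = rot != 0 or shear != 0 or zoom != 1
    if needs_warp:
        img_out = warp(image, tf.inverse, order=1, mode="reflect",
                       preserve_range=True)
        tgt_out = warp(target, tf.inverse, order=0, mode="reflect",
                       preserve_range=True)
    else:
        img_out, tgt_out = image.copy(), target.copy()
    if flip_h:
        img_out, tgt_out = img_out[:, ::-1], tgt_out[:, ::-1]
    if flip_v:
        img_out, tgt_out = img_out[::-1, :], tgt_out[::-1, :]
    return np.ascontiguousarray(img_out * brightness), np.ascontiguousarray(tgt_out)


def normalize_image(raw: np.ndarray) -> np.ndarray:
    """Robust intensity normalization: 1st/99th percentiles to 0/1, clipped.

    Invariant to affine intensity changes a*I + b (a > 0); a constant image
    maps to all zeros.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = np.percentile(raw, [1.0, 99.0])
    if hi <= lo:
        return np.zeros_like(raw)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# numpy U-Net layers
# ---------------------------------------------------------------------------

class _Conv:
    """3x3 (or 1x1) same-padding convolution with im2col forward/backward."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        fan_in = cin * ksize * ksize
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                            size=(cout, cin, ksize, ksize))
        self.b = np.zeros(cout)
        self.k = ksize
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, cin, h, w = x.shape
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,cin,h,w,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, cin * k * k)
        wr = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wr.T + self.b
        self._cache = (cols, (n, cin, h, w))
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray):
        cols, (n, cin, h, w) = self._cache
        k = self.k
        cout = self.w.shape[0]
        gr = g.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        self.gw = (gr.T @ cols).reshape(self.w.shape)
        self.gb = gr.sum(axis=0)
        gcols = (gr @ self.w.reshape(cout, -1)).reshape(n, h, w, cin, k, k)
        gcols = gcols.transpose(0, 3, 1, 2, 4, 5)  # n,cin,h,w,k,k
        pad = k // 2
        gx = np.zeros((n, cin, h + 2 * pad, w + 2 * pad))
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj]
        return gx[:, :, pad:pad + h, pad:pad + w] if pad else gx

    def grads(self):
        return [self.gw, self.gb]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xb = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xb = xb.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xb.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xb, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        n, c, h, w = self._shape
        gb = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gb, self._idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gb.reshape(n, c, h, w)


class _Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x):
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        n, c, h, w = self._shape
        return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class _ConvBlock:
    """Two 3x3 conv + ReLU layers."""

    def __init__(self, cin, cout, rng):
        self.c1, self.r1 = _Conv(cin, cout, 3, rng), _ReLU()
        self.c2, self.r2 = _Conv(cout, cout, 3, rng), _ReLU()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(
            self.r1.forward(self.c1.forward(x))))

    def backward(self, g):
        return self.c1.backward(self.r1.backward(
            self.c2.backward(self.r2.backward(g))))

    def params(self):
        return self.c1.params() + self.c2.params()

    def grads(self):
        return self.c1.grads() + self.c2.grads()


class UNet:
    """Compact encoder-decoder with skip connections on a numpy backend."""

    def __init__(self, depth: int = 2, base_filters: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc: list[_ConvBlock] = []
        self.pools: list[_MaxPool2] = []
        cin = 1
        f = base_filters
        for _ in range(depth):
            self.enc.append(_ConvBlock(cin, f, rng))
            self.pools.append(_MaxPool2())
            cin, f = f, f * 2
        self.bottleneck = _ConvBlock(cin, f, rng)
        self.ups: list[_Upsample2] = []
        self.dec: list[_ConvBlock] = []
        for i in range(depth - 1, -1, -1):
            skip_ch = base_filters * (2**i)
            self.ups.append(_Upsample2())
            self.dec.append(_ConvBlock(f + skip_ch, skip_ch, rng))
            f = skip_ch
        self.head = _Conv(f, 1, 1, rng)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (n, 1, H, W) with H, W multiples of 2**depth; returns logits."""
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append((skip.shape[1], x.shape[1]))
            x = blk.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        g_skips = []
        for i in range(len(self.dec) - 1, -1, -1):
            g = self.dec[i].backward(g)
            sc, _ = self._skip_ch[i]
            g_skip, g_up = g[:, :sc], g[:, sc:]
            g_skips.append(g_skip)
            g = self.ups[i].backward(g_up)
        g = self.bottleneck.backward(g)
        g_skips = g_skips[::-1]  # g_skips[i] pairs with enc stage depth-1-i
        for j in range(self.depth - 1, -1, -1):
            g = self.pools[j].backward(g)
            g = g + g_skips[self.depth - 1 - j]
            g = self.enc[j].backward(g)

    def modules(self):
        return self.enc + [self.bottleneck] + self.dec + [self.head]

    def params(self) -> list[np.ndarray]:
        out = []
        for m in self.modules():
            out += m.params()
        return out

    def grads(self) -> list[np.ndarray]:
        out = []
        for m in self.modules():
            out += m.grads()
        return out


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(z):
    return 0.5 * (1 + np.tanh(0.5 * z))


def _bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable per-pixel binary cross-entropy; returns mean loss
    and the gradient with respect to the logits."""
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = (_sigmoid(z) - t) / z.size
    return float(loss.mean()), grad


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

@dataclass
class ModelHandle:
    """A trained predictor plus its provenance metadata and loss curve."""

    network: UNet
    metadata: dict
    loss_curve: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Single binary weight artifact (.npz) + JSON metadata sidecar."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.network.params())}
        with open(path, "wb") as fh:  # exact filename, no implicit .npz suffix
            np.savez(fh, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = dict(self.metadata)
        meta["loss_curve"] = self.loss_curve
        sidecar.write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelHandle":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".json").read_text())
        net = UNet(depth=meta["depth"], base_filters=meta["base_filters"],
                   seed=0)
        with np.load(path) as data:
            for p, key in zip(net.params(), sorted(data.files,
                                                   key=lambda s: int(s[1:]))):
                p[...] = data[key]
        handle = cls(network=net, metadata=meta,
                     loss_curve=meta.get("loss_curve", []))
        return handle


def train(
    pairs: Sequence[AnnotatedPair],
    tcfg: TrainingConfig | None = None,
    acfg: AugmentationConfig | None = None,
    dilation_px: int = 1,
) -> ModelHandle:
    """Train the pixel classifier on annotated pairs.

    Images are normalized, targets derived (borders zeroed), tiles cut with
    >= half overlap, and each batch is augmented on the fly.  Optimization is
    Adam on per-pixel binary cross-entropy; the per-epoch mean loss is
    recorded in the returned handle.
    """
    tcfg = tcfg or TrainingConfig()
    acfg = acfg or AugmentationConfig()
    if len(pairs) == 0:
        raise ValueError("need at least one annotated pair")
    tiles: list[tuple[np.ndarray, np.ndarray]] = []
    for pair in pairs:
        img = normalize_image(pair.image)
        tgt = make_pixel_target(pair.mask, dilation_px)
        tiles.extend(tile_pairs(img, tgt, tcfg.tile_size))
    rng = np.random.default_rng(tcfg.rng_seed)
    net = UNet(depth=tcfg.depth, base_filters=tcfg.base_filters,
               seed=int(rng.integers(2**31)))
    opt = _Adam(net.params(), lr=tcfg.learning_rate)
    loss_curve: list[float] = []
    steps_per_epoch = math.ceil(len(tiles) / tcfg.batch_size)
    for _ in range(tcfg.epochs):
        order = rng.permutation(len(tiles))
        epoch_losses = []
        for s in range(steps_per_epoch):
            batch_idx = order[s * tcfg.batch_size:(s + 1) * tcfg.batch_size]
            imgs, tgts = [], []
            for i in batch_idx:
                im, tg = augment_pair(tiles[i][0], tiles[i][1], acfg, rng)
                imgs.append(im)
                tgts.append(tg)
            x = np.stack(imgs)[:, None]
            t = np.stack(tgts)[:, None]
            z = net.forward(x)
            loss, gz = _bce_with_logits(z, t)
            net.backward(gz)
            opt.step(net.grads())
            epoch_losses.append(loss)
        loss_curve.append(float(np.mean(epoch_losses)))
    metadata = {
        "depth": tcfg.depth,
        "base_filters": tcfg.base_filters,
        "tile_size": tcfg.tile_size,
        "batch_size": tcfg.batch_size,
        "epochs": tcfg.epochs,
        "learning_rate": tcfg.learning_rate,
        "optimizer": "adam",
        "loss": "binary_cross_entropy",
        "rng_seed": tcfg.rng_seed,
        "n_tiles": len(tiles),
        "steps_per_epoch": steps_per_epoch,
        "total_steps": steps_per_epoch * tcfg.epochs,
        "dilation_px": dilation_px,
    }
    return ModelHandle(network=net, metadata=metadata, loss_curve=loss_curve)


def predict(model: ModelHandle, image: np.ndarray) -> np.ndarray:
    """Whole-image score map in [0, 1], same shape as the input.

    The image is normalized, reflect-padded to a multiple of the network's
    downsampling factor, passed through in one piece (no tiling), and the
    output cropped back.
    """
    img = normalize_image(np.asarray(image))
    h, w = img.shape
    factor = 2 ** model.network.depth
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    z = model.network.forward(img[None, None])
    return _sigmoid(z[0, 0, :h, :w])
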