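"""Encoder-decoder (U-Net style) segmentation network in pure numpy.

The architecture follows the classic design: a contracting pathway of
repeated [3x3 conv + ReLU, 3x3 conv + ReLU, 2x2 max-pool] stages, a
bottleneck double-conv, and an expansive pathway where each stage
upsamples (nearest-neighbor), applies a 2x2 convolution that halves the
feature channels, concatenates the corresponding contracting feature
map (center-cropped when padding is 'valid'), and applies another
double-conv; a final 1x1 convolution and sigmoid give the per-pixel
foreground probability.  Training minimizes binary cross-entropy with
Adam and stops when the validation intersection-over-union changes by
less than a configured delta between consecutive epochs.

Forward, backward and the optimizer are implemented directly on numpy
arrays (im2col convolutions), so training is deterministic for a fixed
seed.  This is meant for desk-scale 2D problems, not GPU-scale volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import BinaryMask2D, MidsagittalSlice


@dataclass
class SegNetConfig:
    """Architecture hyperparameters.

    ``depth`` counts resolution levels (contracting stages + bottleneck);
    channels double per level from ``base_channels``.  Convolutions are
    3x3 and pooling 2x2, as in the original design; ``padding`` is
    'same' (default, keeps the output at input size) or 'valid'
    (unpadded convolutions with skip-connection cropping).
    """

    depth: int = 3
    base_channels: int = 8
    conv_size: int = 3
    pool_size: int = 2
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.conv_size != 3 or self.pool_size != 2:
            raise ValueError("architecture is fixed to 3x3 convs and 2x2 pooling")
        if self.padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")


@dataclass
class TrainConfig:
    """Optimization settings: Adam at 1e-4, up to 250 epochs, 80/20 split,
    early stop when consecutive validation-IOU change falls below
    ``iou_delta_stop``."""

    learning_rate: float = 1e-4
    max_epochs: int = 250
    iou_delta_stop: float = 1e-4
    train_fraction: float = 0.8
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class ShapeError(ValueError):
    """Input size incompatible with the network (odd dims at a pooling,
    or a feature map shrinking to nothing under valid padding)."""


# ---------------------------------------------------------------------------
# layers


class _Conv2d:
    """k x k convolution via im2col, with He-initialized weights."""

    def __init__(self, in_ch: int, out_ch: int, k: int, padding: str, rng) -> None:
        fan_in = in_ch * k * k
        # float32 throughout: halves memory traffic, ample precision for SGD
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k = k
        self.padding = padding
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def _pads(self) -> tuple[int, int]:
        if self.padding == "same":
            total = self.k - 1
            return total // 2, total - total // 2
        return 0, 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pb, pa = self._pads()
        if pb or pa:
            xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa)))
        else:
            xp = x
        n, c, hp, wp = xp.shape
        ho, wo = hp - self.k + 1, wp - self.k + 1
        if ho <= 0 or wo <= 0:
            raise ShapeError(
                f"feature map {x.shape[2:]}, kernel {self.k} (valid): output empty"
            )
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # n,c,ho,wo,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * self.k**2)
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = cols @ wmat.T + self.b
        if train:
            self._cache = (cols, x.shape, (n, ho, wo))
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (n, ho, wo) = self._cache
        o = dy.shape[1]
        dym = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        self.gw += (dym.T @ cols).reshape(self.w.shape)
        self.gb += dym.sum(axis=0)
        dcols = dym @ self.w.reshape(o, -1)  # (n*ho*wo, c*k*k)
        c = x_shape[1]
        dwin = dcols.reshape(n, ho, wo, c, self.k, self.k)
        pb, pa = self._pads()
        hp, wp = x_shape[2] + pb + pa, x_shape[3] + pb + pa
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + ho, j : j + wo] += dwin[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if pb or pa:
            dxp = dxp[:, :, pb : hp - pa, pb : wp - pa]
        return dxp

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class _ReLU:
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2:
    def forward(self, x, train):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ShapeError(
                f"feature map {h}x{w} has odd dimensions at a 2x2 pooling; "
                "choose an input size divisible by 2**(depth-1) or reduce depth"
            )
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._am = xr.argmax(axis=-1)
            self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._in_shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(flat, self._am[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(n, c, h, w)


class _Upsample2:
    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _center_crop(x: np.ndarray, h: int, w: int) -> tuple[np.ndarray, tuple[int, int]]:
    dh, dw = x.shape[2] - h, x.shape[3] - w
    if dh < 0 or dw < 0:
        raise ShapeError("skip connection smaller than decoder feature map")
    t, l = dh // 2, dw // 2
    return x[:, :, t : t + h, l : l + w], (t, l)


# ---------------------------------------------------------------------------
# network


class UNet:
    """The assembled network.  Use :func:`build_segnet` to construct."""

    def __init__(self, cfg: SegNetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        pad = cfg.padding
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        self.enc: list[list] = []
        in_ch = 1
        for i in range(cfg.depth - 1):
            self.enc.append(
                [
                    _Conv2d(in_ch, ch[i], 3, pad, rng),
                    _ReLU(),
                    _Conv2d(ch[i], ch[i], 3, pad, rng),
                    _ReLU(),
                ]
            )
            in_ch = ch[i]
        self.pools = [_MaxPool2() for _ in range(cfg.depth - 1)]
        self.bottleneck = [
            _Conv2d(in_ch, ch[-1], 3, pad, rng),
            _ReLU(),
            _Conv2d(ch[-1], ch[-1], 3, pad, rng),
            _ReLU(),
        ]
        self.ups: list[_Upsample2] = []
        self.upconvs: list[_Conv2d] = []
        self.dec: list[list] = []
        for i in range(cfg.depth - 2, -1, -1):
            self.ups.append(_Upsample2())
            self.upconvs.append(_Conv2d(ch[i + 1], ch[i], 2, pad, rng))
            self.dec.append(
                [
                    _Conv2d(2 * ch[i], ch[i], 3, pad, rng),
                    _ReLU(),
                    _Conv2d(ch[i], ch[i], 3, pad, rng),
                    _ReLU(),
                ]
            )
        self.final = _Conv2d(ch[0], 1, 1, pad, rng)

    # -- plumbing -----------------------------------------------------------

    def _conv_layers(self) -> list[_Conv2d]:
        layers = []
        for block in self.enc + [self.bottleneck] + self.dec:
            layers += [l for l in block if isinstance(l, _Conv2d)]
        layers += self.upconvs + [self.final]
        return layers

    def n_parameters(self) -> int:
        return sum(l.n_params for l in self._conv_layers())

    def parameters(self):
        out = []
        for l in self._conv_layers():
            out.extend(l.params())
        return out

    def zero_grad(self) -> None:
        for l in self._conv_layers():
            l.gw[:] = 0.0
            l.gb[:] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self._conv_layers():
            out += [l.w.copy(), l.b.copy()]
        return out

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        layers = self._conv_layers()
        if len(arrays) != 2 * len(layers):
            raise ValueError("weight list does not match the architecture")
        for l, w, b in zip(layers, arrays[0::2], arrays[1::2]):
            l.w = w.astype(np.float32)
            l.b = b.astype(np.float32)

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _run(block, x, train):
        for layer in block:
            x = layer.forward(x, train)
        return x

    @staticmethod
    def _run_back(block, dy):
        for layer in reversed(block):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch shaped (N, 1, H, W)."""
        skips = []
        h = np.ascontiguousarray(x, dtype=np.float32)
        for block, pool in zip(self.enc, self.pools):
            h = self._run(block, h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self._run(self.bottleneck, h, train)
        self._crops = []
        for up, upconv, dec, skip in zip(
            self.ups, self.upconvs, self.dec, reversed(skips)
        ):
            h = up.forward(h, train)
            h = upconv.forward(h, train)
            s, off = _center_crop(skip, h.shape[2], h.shape[3])
            self._crops.append((skip.shape, off, h.shape[1]))
            h = np.concatenate([s, h], axis=1)
            h = self._run(dec, h, train)
        return self.final.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.final.backward(dlogits)
        skip_grads = []
        for dec, upconv, up, (skip_shape, off, ch_up) in zip(
            reversed(self.dec), reversed(self.upconvs), reversed(self.ups),
            reversed(self._crops),
        ):
            dcat = self._run_back(dec, dy)
            ch_skip = dcat.shape[1] - ch_up
            dskip_crop, dup = dcat[:, :ch_skip], dcat[:, ch_skip:]
            dskip = np.zeros(skip_shape, dtype=np.float32)
            t, l = off
            h, w = dskip_crop.shape[2], dskip_crop.shape[3]
            dskip[:, :, t : t + h, l : l + w] = dskip_crop
            skip_grads.append(dskip)
            dy = up.backward(upconv.backward(dup))
        dy = self._run_back(self.bottleneck, dy)
        # skip_grads were collected shallowest-first; encoders unwind deepest-first
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            dy = pool.backward(dy) + dskip
            dy = self._run_back(block, dy)

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Sigmoid probability maps, computed in evaluation batches."""
        outs = []
        for start in range(0, x.shape[0], batch_size):
            z = self.forward(x[start : start + batch_size], train=False)
            outs.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(outs, axis=0)


def build_segnet(cfg: SegNetConfig, seed: int = 0) -> UNet:
    """Construct an untrained network from its configuration."""
    return UNet(cfg, seed)


# ---------------------------------------------------------------------------
# training


@dataclass
class SegWeights:
    """Trained parameters plus the config that produced them and the
    per-epoch validation IOU log."""

    config: SegNetConfig
    arrays: list[np.ndarray]
    iou_log: list[float] = field(default_factory=list)
    train_config: TrainConfig | None = None

    def to_model(self) -> UNet:
        net = UNet(self.config)
        net.set_weights(self.arrays)
        return net

    def save(self, path: str | Path) -> None:
        """Serialize as .npz with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, *self.arrays)
        sidecar = {
            "config": self.config.__dict__,
            "iou_log": self.iou_log,
            "train_config": self.train_config.__dict__ if self.train_config else None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SegWeights":
        path = Path(path)
        with np.load(path.suffix == ".npz" and path or path.with_suffix(".npz")) as z:
            arrays = [z[k] for k in z.files]
        meta = json.loads(path.with_suffix(".json").read_text())
        tc = meta.get("train_config")
        return cls(
            SegNetConfig(**meta["config"]),
            arrays,
            meta.get("iou_log", []),
            TrainConfig(**tc) if tc else None,
        )


class _Adam:
    def __init__(self, lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p, _ in params]
            self.v = [np.zeros_like(p) for p, _ in params]
        self.t += 1
        for i, (p, g) in enumerate(params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def iou(a: BinaryMask2D | np.ndarray, b: BinaryMask2D | np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 when both empty."""
    pa = a.pixels if isinstance(a, BinaryMask2D) else np.asarray(a)
    pb = b.pixels if isinstance(b, BinaryMask2D) else np.asarray(b)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    pa, pb = pa.astype(bool), pb.astype(bool)
    union = np.logical_or(pa, pb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pa, pb).sum() / union)


def _crop_target(t: np.ndarray, h: int, w: int) -> np.ndarray:
    dh, dw = t.shape[-2] - h, t.shape[-1] - w
    return t[..., dh // 2 : dh // 2 + h, dw // 2 : dw // 2 + w]


def _bce_and_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    # stable BCE from logits: log(1+exp(-|z|)) + max(z,0) - z*t
    z = logits
    loss = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * targets)
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss), ((p - targets) / z.size).astype(z.dtype)


def _val_iou(net: UNet, x: np.ndarray, y: np.ndarray) -> float:
    """Mean per-image IOU of thresholded (>0.5) predictions."""
    proba = net.predict_proba(x)
    pred = proba > 0.5
    t = _crop_target(y, pred.shape[2], pred.shape[3])
    scores = [iou(pred[i, 0], t[i, 0]) for i in range(x.shape[0])]
    return float(np.mean(scores))


def train_segmenter(
    pairs: list[tuple[MidsagittalSlice, BinaryMask2D]],
    cfg: TrainConfig | None = None,
    net_cfg: SegNetConfig | None = None,
) -> SegWeights:
    """Train the segmentation network on image/mask pairs.

    The data are split train/validation by ``cfg.train_fraction``
    (seeded shuffle); minibatch BCE is minimized with Adam; after each
    epoch the validation IOU is logged and training stops when its
    change from the previous epoch is below ``cfg.iou_delta_stop`` (the
    pre-training IOU serves as the epoch-0 baseline) or at
    ``cfg.max_epochs``.
    """
    cfg = cfg or TrainConfig()
    net_cfg = net_cfg or SegNetConfig()
    if len(pairs) < 10:
        raise ValueError("training needs at least 10 image/mask pairs")
    shapes = {img.shape for img, _ in pairs} | {m.shape for _, m in pairs}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous image/mask shapes: {sorted(shapes)}")

    x = np.stack([img.pixels for img, _ in pairs])[:, None, :, :].astype(np.float32)
    y = np.stack([m.pixels for _, m in pairs])[:, None, :, :].astype(np.float32)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pairs))
    n_train = max(1, int(round(cfg.train_fraction * len(pairs))))
    tr, va = order[:n_train], order[n_train:]
    if va.size == 0:
        tr, va = order[:-1], order[-1:]
    x_tr, y_tr, x_va, y_va = x[tr], y[tr], x[va], y[va]

    net = UNet(net_cfg, seed=int(rng.integers(0, 2**31 - 1)))
    opt = _Adam(cfg.learning_rate)
    prev_iou = _val_iou(net, x_va, y_va)
    log: list[float] = []
    for _epoch in range(cfg.max_epochs):
        idx = rng.permutation(len(tr))
        for start in range(0, idx.size, cfg.batch_size):
            b = idx[start : start + cfg.batch_size]
            net.zero_grad()
            logits = net.forward(x_tr[b], train=True)
            t = _crop_target(y_tr[b], logits.shape[2], logits.shape[3])
            _, dz = _bce_and_grad(logits, t)
            net.backward(dz)
            opt.step(net.parameters())
        cur = _val_iou(net, x_va, y_va)
        log.append(cur)
        if abs(cur - prev_iou) < cfg.iou_delta_stop:
            break
        prev_iou = cur
    return SegWeights(net_cfg, net.get_weights(), log, cfg)


def segment_slice(
    image: MidsagittalSlice, weights: SegWeights | UNet, threshold: float = 0.5
) -> BinaryMask2D:
    """Segment one slice: probability map thresholded at > 0.5.

    Under 'valid' padding the input is reflect-padded so that the output
    grid matches the input; under 'same' padding shapes already agree.
    The frame tag and pixel size are copied from the input.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    net = weights.to_model() if isinstance(weights, SegWeights) else weights
    x = image.pixels[None, None, :, :]
    if net.cfg.padding == "valid":
        x = _pad_for_valid(net, x)
    proba = net.predict_proba(x)[0, 0]
    if proba.shape != image.shape:
        dh, dw = proba.shape[0] - image.shape[0], proba.shape[1] - image.shape[1]
        if dh < 0 or dw < 0:
            raise ShapeError("network output smaller than input after padding")
        proba = proba[dh // 2 : dh // 2 + image.shape[0], dw // 2 : dw // 2 + image.shape[1]]
    return BinaryMask2D(
        (proba > threshold).astype(np.uint8), image.pixel_size_mm, image.frame
    )


def _simulate_output(cfg: SegNetConfig, size: int) -> int | None:
    """Output edge length for a square input, or None if incompatible."""
    shrink = 4 if cfg.padding == "valid" else 0
    s = size
    for _ in range(cfg.depth - 1):
        s -= shrink
        if s <= 0 or s % 2:
            return None
        s //= 2
    s -= shrink
    if s <= 0:
        return None
    for _ in range(cfg.depth - 1):
        s *= 2
        if cfg.padding == "valid":
            s -= 1
        s -= shrink
        if s <= 0:
            return None
    return s


def _pad_for_valid(net: UNet, x: np.ndarray) -> np.ndarray:
    h, w = x.shape[2], x.shape[3]
    target = max(h, w)
    for size in range(target, target + 4 * 2**net.cfg.depth + 64):
        out = _simulate_output(net.cfg, size)
        if out is not None and out >= target:
            ph, pw = size - h, size - w
            return np.pad(
                x,
                ((0, 0), (0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)),
                mode="reflect",
            )
    raise ShapeError(
        f"no compatible padded size found for input {h}x{w} at depth {net.cfg.depth}"
    )
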