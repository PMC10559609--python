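"""U-Net lesion segmentation implemented in NumPy with manual backprop.

Architecture (fixed depth 4, matching the classic U-Net encoder/decoder):

* encoder: four blocks of two 3×3 convolutions + ReLU, each block followed
  by 2×2 max pooling with stride 2;
* bottleneck: two 3×3 convolutions + ReLU;
* decoder: four blocks of 2× nearest-neighbour upsampling + 3×3 convolution,
  concatenation with the matching encoder feature map, then two 3×3
  convolutions + ReLU;
* head: one 1×1 convolution to a single cancer-vs-background logit per
  pixel, squashed by a sigmoid.

All 3×3 convolutions use "same" padding, so the output mask has the input's
spatial size and skip connections concatenate without cropping.  Channel
widths double per level from ``base_channels``.  Input sizes must be
divisible by 16 (four pooling halvings).

Training uses pixel-wise binary cross-entropy (optionally + Dice), Adam,
and on-the-fly augmentation (horizontal flips, rotations, colour jitter,
blur, noise).  An optional modality-conditioned variant adds a learned
per-modality embedding to the bottleneck via a linear layer, merging
white-light and narrow-band cues; the default is a single pooled network
trained on both modalities.

Everything is float32 and seeded: two runs with the same config and seed
produce identical loss histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _resize

from .io import Frame, Modality

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "SegmentationResult",
    "UNet",
    "build_model",
    "train",
    "train_arrays",
    "predict",
    "predict_batch",
    "render_heatmap",
    "load_model",
]

DEPTH = 4  # pooling halvings; fixed by the architecture


@dataclass(frozen=True)
class UNetSpec:
    base_channels: int = 8
    input_size: tuple[int, int] = (512, 512)
    in_channels: int = 3
    modality_fusion: bool = False  # per-modality bottleneck embedding

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 16 "
                f"(four 2x2 pooling halvings)"
            )
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "bce"  # "bce" or "bce+dice"
    augment_flip: bool = True
    augment_rotation: bool = False
    augment_color_jitter: bool = False
    augment_blur: bool = False
    augment_noise: bool = False
    rotation_max_deg: float = 15.0
    jitter_strength: float = 0.1
    noise_sd: float = 0.02
    seed: int = 0
    modality: str = "all"  # "all" (pooled), "WLI" (model W), "NBI" (model N)
    patience: int = 0  # early stopping on verification loss; 0 = off

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class SegmentationResult:
    prob_map: np.ndarray  # (H, W) in [0, 1] at model input resolution
    binary_mask: np.ndarray  # (H, W) {0,1}; 1 where prob_map > threshold
    source_size: tuple[int, int]  # original frame (H, W)
    threshold: float = 0.5


# ------------------------------------------------------------ layer kernels

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches for 3x3 same-padded conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * 9, h * w)


def _col2im(dcols: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    """Adjoint of _im2col: (N, C*9, H*W) -> (N, C, H, W)."""
    n = dcols.shape[0]
    d = dcols.reshape(n, c, 3, 3, h, w)
    out = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            out[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return out[:, :, 1 : 1 + h, 1 : 1 + w]


def _conv3x3_forward(x, W, b):
    n, c, h, w = x.shape
    cols = _im2col(x)
    y = np.matmul(W, cols) + b[None, :, None]  # (N, O, H*W)
    return y.reshape(n, -1, h, w), (cols, x.shape)


def _conv3x3_backward(dy, W, cache):
    cols, xshape = cache
    n, c, h, w = xshape
    dyf = dy.reshape(dy.shape[0], dy.shape[1], -1)
    dW = np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
    db = dyf.sum(axis=(0, 2))
    dcols = np.matmul(W.T, dyf)
    dx = _col2im(dcols, c, h, w)
    return dx, dW, db


def _conv1x1_forward(x, W, b):
    n, c, h, w = x.shape
    y = np.matmul(W, x.reshape(n, c, h * w)) + b[None, :, None]
    return y.reshape(n, -1, h, w), x


def _conv1x1_backward(dy, W, x):
    n, c, h, w = x.shape
    dyf = dy.reshape(n, dy.shape[1], h * w)
    xf = x.reshape(n, c, h * w)
    dW = np.matmul(dyf, xf.transpose(0, 2, 1)).sum(axis=0)
    db = dyf.sum(axis=(0, 2))
    dx = np.matmul(W.T, dyf).reshape(n, c, h, w)
    return dx, dW, db


def _relu_forward(x):
    y = np.maximum(x, 0)
    return y, y


def _relu_backward(dy, y):
    return dy * (y > 0)


def _maxpool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def _maxpool_backward(dy, cache):
    idx, (n, c, h, w) = cache
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(n, c, h, w)


def _upsample_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ------------------------------------------------------------------- model

class UNet:
    """Depth-4 U-Net with single-logit head; parameters in ``self.params``."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self._caches = None
        rng = np.random.default_rng(seed)
        b = spec.base_channels
        self.enc_channels = [b * 2**i for i in range(DEPTH)]  # per level
        self.bottleneck_channels = b * 2**DEPTH

        def he(fan_in, shape):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        cin = spec.in_channels
        for i, cout in enumerate(self.enc_channels):
            self.params[f"enc{i}_c1_W"] = he(cin * 9, (cout, cin * 9))
            self.params[f"enc{i}_c1_b"] = np.zeros(cout, np.float32)
            self.params[f"enc{i}_c2_W"] = he(cout * 9, (cout, cout * 9))
            self.params[f"enc{i}_c2_b"] = np.zeros(cout, np.float32)
            cin = cout
        cb = self.bottleneck_channels
        self.params["bot_c1_W"] = he(cin * 9, (cb, cin * 9))
        self.params["bot_c1_b"] = np.zeros(cb, np.float32)
        self.params["bot_c2_W"] = he(cb * 9, (cb, cb * 9))
        self.params["bot_c2_b"] = np.zeros(cb, np.float32)
        if spec.modality_fusion:
            # learned embedding per modality, merged by a linear map
            self.params["mod_embed"] = np.zeros((2, cb), np.float32)
            self.params["mod_W"] = he(cb, (cb, cb))
        cin = cb
        for i in reversed(range(DEPTH)):
            ci = self.enc_channels[i]
            self.params[f"dec{i}_up_W"] = he(cin * 9, (ci, cin * 9))
            self.params[f"dec{i}_up_b"] = np.zeros(ci, np.float32)
            self.params[f"dec{i}_c1_W"] = he(2 * ci * 9, (ci, 2 * ci * 9))
            self.params[f"dec{i}_c1_b"] = np.zeros(ci, np.float32)
            self.params[f"dec{i}_c2_W"] = he(ci * 9, (ci, ci * 9))
            self.params[f"dec{i}_c2_b"] = np.zeros(ci, np.float32)
            cin = ci
        self.params["head_W"] = he(cin, (1, cin))
        self.params["head_b"] = np.zeros(1, np.float32)

    # -- forward ----------------------------------------------------------
    def forward(self, x: np.ndarray, modality_idx: Optional[np.ndarray] = None,
                keep_caches: bool = False) -> np.ndarray:
        """x: (N, 3, H, W) float32 in [0,1] -> logits (N, 1, H, W)."""
        p = self.params
        caches: dict = {}
        skips = []
        h = x
        for i in range(DEPTH):
            h, c1 = _conv3x3_forward(h, p[f"enc{i}_c1_W"], p[f"enc{i}_c1_b"])
            h, r1 = _relu_forward(h)
            h, c2 = _conv3x3_forward(h, p[f"enc{i}_c2_W"], p[f"enc{i}_c2_b"])
            h, r2 = _relu_forward(h)
            skips.append(h)
            h, mp = _maxpool_forward(h)
            caches[f"enc{i}"] = (c1, r1, c2, r2, mp)
        h, c1 = _conv3x3_forward(h, p["bot_c1_W"], p["bot_c1_b"])
        h, r1 = _relu_forward(h)
        h, c2 = _conv3x3_forward(h, p["bot_c2_W"], p["bot_c2_b"])
        h, r2 = _relu_forward(h)
        caches["bot"] = (c1, r1, c2, r2)
        if self.spec.modality_fusion:
            if modality_idx is None:
                modality_idx = np.zeros(x.shape[0], dtype=int)
            emb = p["mod_embed"][modality_idx] @ p["mod_W"].T  # (N, Cb)
            h = h + emb[:, :, None, None]
            caches["fusion_idx"] = modality_idx
        for i in reversed(range(DEPTH)):
            h = _upsample_forward(h)
            h, cu = _conv3x3_forward(h, p[f"dec{i}_up_W"], p[f"dec{i}_up_b"])
            h, ru = _relu_forward(h)
            ci = self.enc_channels[i]
            h = np.concatenate([skips[i], h], axis=1)
            h, c1 = _conv3x3_forward(h, p[f"dec{i}_c1_W"], p[f"dec{i}_c1_b"])
            h, r1 = _relu_forward(h)
            h, c2 = _conv3x3_forward(h, p[f"dec{i}_c2_W"], p[f"dec{i}_c2_b"])
            h, r2 = _relu_forward(h)
            caches[f"dec{i}"] = (cu, ru, c1, r1, c2, r2, ci)
        logits, ch = _conv1x1_forward(h, p["head_W"], p["head_b"])
        caches["head"] = ch
        if keep_caches:
            self._caches = caches
        return logits

    # -- backward ---------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss wrt every parameter, given dL/dlogits.

        Must follow a ``forward(..., keep_caches=True)`` call.
        """
        p = self.params
        caches = self._caches
        grads = {k: None for k in p}
        dh, grads["head_W"], grads["head_b"] = _conv1x1_backward(
            dlogits, p["head_W"], caches["head"]
        )
        dskips = [None] * DEPTH
        for i in range(DEPTH):
            cu, ru, c1, r1, c2, r2, ci = caches[f"dec{i}"]
            dh = _relu_backward(dh, r2)
            dh, grads[f"dec{i}_c2_W"], grads[f"dec{i}_c2_b"] = _conv3x3_backward(
                dh, p[f"dec{i}_c2_W"], c2
            )
            dh = _relu_backward(dh, r1)
            dh, grads[f"dec{i}_c1_W"], grads[f"dec{i}_c1_b"] = _conv3x3_backward(
                dh, p[f"dec{i}_c1_W"], c1
            )
            dskips[i] = dh[:, :ci]
            dh = dh[:, ci:]
            dh = _relu_backward(dh, ru)
            dh, grads[f"dec{i}_up_W"], grads[f"dec{i}_up_b"] = _conv3x3_backward(
                dh, p[f"dec{i}_up_W"], cu
            )
            dh = _upsample_backward(dh)
        if self.spec.modality_fusion:
            idx = caches["fusion_idx"]
            demb_out = dh.sum(axis=(2, 3))  # (N, Cb)
            grads["mod_W"] = np.einsum(
                "nc,nd->cd", demb_out, p["mod_embed"][idx], optimize=True
            )
            dembed = demb_out @ p["mod_W"]  # (N, Cb)
            ge = np.zeros_like(p["mod_embed"])
            np.add.at(ge, idx, dembed)
            grads["mod_embed"] = ge
        c1, r1, c2, r2 = caches["bot"]
        dh = _relu_backward(dh, r2)
        dh, grads["bot_c2_W"], grads["bot_c2_b"] = _conv3x3_backward(dh, p["bot_c2_W"], c2)
        dh = _relu_backward(dh, r1)
        dh, grads["bot_c1_W"], grads["bot_c1_b"] = _conv3x3_backward(dh, p["bot_c1_W"], c1)
        for i in reversed(range(DEPTH)):
            c1, r1, c2, r2, mp = caches[f"enc{i}"]
            dh = _maxpool_backward(dh, mp)
            dh = dh + dskips[i]
            dh = _relu_backward(dh, r2)
            dh, grads[f"enc{i}_c2_W"], grads[f"enc{i}_c2_b"] = _conv3x3_backward(
                dh, p[f"enc{i}_c2_W"], c2
            )
            dh = _relu_backward(dh, r1)
            dh, grads[f"enc{i}_c1_W"], grads[f"enc{i}_c1_b"] = _conv3x3_backward(
                dh, p[f"enc{i}_c1_W"], c1
            )
        self._caches = None
        return grads

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path).with_suffix(".npz")
        np.savez(path, **self.params)
        sidecar = {
            "spec": {
                "base_channels": self.spec.base_channels,
                "input_size": list(self.spec.input_size),
                "in_channels": self.spec.in_channels,
                "modality_fusion": self.spec.modality_fusion,
            }
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> UNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    s = sidecar["spec"]
    spec = UNetSpec(
        base_channels=s["base_channels"],
        input_size=tuple(s["input_size"]),
        in_channels=s["in_channels"],
        modality_fusion=s["modality_fusion"],
    )
    model = UNet(spec)
    with np.load(path.with_suffix(".npz")) as data:
        for k in model.params:
            model.params[k] = data[k]
    return model


def build_model(spec: UNetSpec, seed: int = 0) -> UNet:
    """Seeded construction; raises on input sizes not divisible by 16."""
    return UNet(spec, seed=seed)


# ------------------------------------------------------------------ losses

def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(logits: np.ndarray, targets: np.ndarray,
                      dice_weight: float = 0.0):
    """Mean pixel-wise binary cross-entropy (+ optional soft Dice)."""
    z = logits
    t = targets
    n = z.size
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    probs = _sigmoid(z)
    grad = (probs - t) / n
    if dice_weight > 0:
        eps = 1.0
        inter = float((probs * t).sum())
        denom = float(probs.sum() + t.sum()) + eps
        dice = 1.0 - (2 * inter + eps) / denom
        ddice_dp = (-2 * t * denom + (2 * inter + eps)) / denom**2
        grad = grad + dice_weight * ddice_dp * probs * (1 - probs) / 1.0
        loss = loss + dice_weight * dice
    return loss, grad.astype(np.float32)


# ------------------------------------------------------------------- Adam

class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-2):
        self.lr = lr

    def step(self, params, grads):
        for k, g in grads.items():
            if g is not None:
                params[k] -= self.lr * g


# ----------------------------------------------------------- augmentation

def augment_pair(image: np.ndarray, mask: np.ndarray, cfg: TrainConfig,
                 rng: np.random.Generator):
    """Apply the configured augmentations to one (C,H,W) image / (H,W) mask.

    Geometric transforms are applied identically to image and mask (mask
    with nearest-neighbour semantics); photometric transforms touch the
    image only.
    """
    img = image
    msk = mask
    if cfg.augment_flip and rng.random() < 0.5:
        img = img[:, :, ::-1]
        msk = msk[:, ::-1]
    if cfg.augment_rotation:
        from scipy.ndimage import rotate as ndrotate

        deg = float(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg))
        img = np.stack(
            [ndrotate(ch, deg, reshape=False, order=1, mode="nearest") for ch in img]
        )
        msk = ndrotate(msk, deg, reshape=False, order=0, mode="nearest")
    if cfg.augment_color_jitter:
        scale = rng.uniform(1 - cfg.jitter_strength, 1 + cfg.jitter_strength, (3, 1, 1))
        shift = rng.uniform(-cfg.jitter_strength / 2, cfg.jitter_strength / 2, (3, 1, 1))
        img = np.clip(img * scale + shift, 0, 1)
    if cfg.augment_blur and rng.random() < 0.5:
        from scipy.ndimage import gaussian_filter

        sigma = float(rng.uniform(0.3, 1.0))
        img = np.stack([gaussian_filter(ch, sigma) for ch in img])
    if cfg.augment_noise:
        img = np.clip(img + rng.normal(0, cfg.noise_sd, img.shape), 0, 1)
    return np.ascontiguousarray(img, dtype=np.float32), np.ascontiguousarray(
        msk, dtype=np.float32
    )


# ---------------------------------------------------------------- training

def _prep_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """uint8 (H, W, 3) -> float32 (3, h, w) in [0,1], bilinear resize."""
    if image.shape[:2] != size:
        image = _resize(image, size, order=1, preserve_range=True, anti_aliasing=True)
    return np.ascontiguousarray(image.transpose(2, 0, 1), dtype=np.float32) / 255.0


def _prep_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """{0,1} (H, W) -> float32 (h, w), nearest-neighbour resize."""
    if mask.shape != size:
        mask = _resize(mask.astype(float), size, order=0, preserve_range=True,
                       anti_aliasing=False)
    return np.ascontiguousarray(mask, dtype=np.float32)


def train_arrays(
    model: UNet,
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    cfg: TrainConfig,
    val_images: Sequence[np.ndarray] = (),
    val_masks: Sequence[np.ndarray] = (),
    modalities: Optional[Sequence[Modality]] = None,
) -> tuple[UNet, list[float]]:
    """Train on in-memory uint8 images and {0,1} masks.

    Images are resized to the model's input size (bilinear; masks nearest
    neighbour).  Returns the model (best verification weights if a
    verification set is given) and the per-epoch training loss history.
    Aborts with ``FloatingPointError`` on a non-finite loss.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    size = model.spec.input_size
    X = np.stack([_prep_image(np.asarray(im), size) for im in images])
    Y = np.stack([_prep_mask(np.asarray(m), size) for m in masks])
    mod_idx = (
        np.array([0 if Modality(m) is Modality.WLI else 1 for m in modalities])
        if modalities is not None
        else np.zeros(len(images), dtype=int)
    )
    Xv = np.stack([_prep_image(np.asarray(im), size) for im in val_images]) if len(val_images) else None
    Yv = np.stack([_prep_mask(np.asarray(m), size) for m in val_masks]) if len(val_masks) else None

    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer.lower() == "adam":
        opt = Adam(model.params, lr=cfg.learning_rate)
    elif cfg.optimizer.lower() == "sgd":
        opt = SGD(model.params, lr=cfg.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    dice_w = 0.5 if cfg.loss == "bce+dice" else 0.0
    if cfg.loss not in ("bce", "bce+dice"):
        raise ValueError(f"unknown loss {cfg.loss!r}")

    any_aug = (cfg.augment_flip or cfg.augment_rotation or cfg.augment_color_jitter
               or cfg.augment_blur or cfg.augment_noise)
    history: list[float] = []
    best_val = np.inf
    best_params = None
    bad_epochs = 0
    n = len(X)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb = X[sel]
            yb = Y[sel]
            if any_aug:
                pairs = [augment_pair(xb[i], yb[i], cfg, rng) for i in range(len(sel))]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs])
            logits = model.forward(xb, modality_idx=mod_idx[sel], keep_caches=True)
            loss, dlogits = bce_loss_and_grad(logits, yb[:, None], dice_weight=dice_w)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            grads = model.backward(dlogits)
            opt.step(model.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if Xv is not None:
            val_losses = []
            for start in range(0, len(Xv), cfg.batch_size):
                logits = model.forward(Xv[start : start + cfg.batch_size])
                l, _ = bce_loss_and_grad(logits, Yv[start : start + cfg.batch_size][:, None])
                val_losses.append(l * min(cfg.batch_size, len(Xv) - start))
            val_loss = float(np.sum(val_losses) / len(Xv))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if cfg.patience and bad_epochs >= cfg.patience:
                    break
    if best_params is not None:
        model.params = best_params
    return model, history


def train(model: UNet, manifest, cfg: TrainConfig, data_root=None):
    """Train from a dataset manifest (train split; verification split for
    model selection), honouring the modality filter: ``"WLI"`` trains a
    white-light-only model (model W), ``"NBI"`` a narrow-band-only model
    (model N), ``"all"`` the pooled multimodal model.
    """
    from .io import DatasetManifest, rasterize_annotation, read_annotation, read_image

    if not isinstance(manifest, DatasetManifest):
        raise TypeError("manifest must be a DatasetManifest")
    root = Path(data_root) if data_root is not None else Path(".")
    mod = None if cfg.modality == "all" else Modality(cfg.modality)

    def load_split(split):
        imgs, msks, mods = [], [], []
        for rec in manifest.subset(split=split, modality=mod):
            img = read_image(root / rec.frame_path)
            if rec.annotation_path:
                ann = read_annotation(root / rec.annotation_path)
                msk = rasterize_annotation(ann, img.shape[0], img.shape[1])
            else:
                msk = np.zeros(img.shape[:2], dtype=np.uint8)
            imgs.append(img)
            msks.append(msk)
            mods.append(rec.modality)
        return imgs, msks, mods

    tr_imgs, tr_msks, tr_mods = load_split("train")
    if not tr_imgs:
        raise ValueError("empty training split after modality filtering")
    va_imgs, va_msks, _ = load_split("verification")
    return train_arrays(model, tr_imgs, tr_msks, cfg, va_imgs, va_msks,
                        modalities=tr_mods)


# --------------------------------------------------------------- inference

def predict_batch(model: UNet, images: np.ndarray,
                  modality_idx: Optional[np.ndarray] = None) -> np.ndarray:
    """(N, H, W, 3) uint8 (at the model input size) -> (N, h, w) prob maps."""
    x = np.ascontiguousarray(images.transpose(0, 3, 1, 2), dtype=np.float32) / 255.0
    logits = model.forward(x, modality_idx=modality_idx)
    return _sigmoid(logits[:, 0])


def predict(model: UNet, frame: Frame, probability_threshold: float = 0.5) -> SegmentationResult:
    """Segment one frame; output at model input resolution.

    ``binary_mask = 1`` exactly where ``prob_map > probability_threshold``
    (strict, so threshold 1.0 yields an empty mask).
    """
    img = np.asarray(frame.image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("predict expects an RGB frame")
    source_size = img.shape[:2]
    x = _prep_image(img, model.spec.input_size)[None]
    mod_idx = np.array([0 if frame.modality is Modality.WLI else 1])
    logits = model.forward(x, modality_idx=mod_idx)
    prob = _sigmoid(logits[0, 0])
    mask = (prob > probability_threshold).astype(np.uint8)
    return SegmentationResult(prob_map=prob, binary_mask=mask,
                              source_size=tuple(source_size),
                              threshold=probability_threshold)


def render_heatmap(result: SegmentationResult, frame: Frame,
                   alpha: float = 0.4, cmap: str = "jet") -> np.ndarray:
    """Colour-mapped probability map alpha-blended over the frame.

    Warm colours mark high predicted cancer probability.  Output is 8-bit
    RGB at the frame's own resolution.
    """
    import matplotlib

    img = np.asarray(frame.image, dtype=np.float32)
    prob = result.prob_map
    if prob.shape != img.shape[:2]:
        prob = _resize(prob, img.shape[:2], order=1, preserve_range=True)
    colors = matplotlib.colormaps[cmap](np.clip(prob, 0, 1))[..., :3] * 255.0
    out = (1 - alpha) * img + alpha * colors
    return np.clip(out, 0, 255).astype(np.uint8)
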