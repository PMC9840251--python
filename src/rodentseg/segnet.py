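"""3D U-Net segmentation engine and the stepwise brain -> tumor cascade.

The network is the classic volumetric encoder-decoder: per level two
3x3x3 convolutions + ReLU followed by 2x max-pooling on the way down, 2x
nearest-neighbor up-sampling with skip concatenation from the matching
encoder level on the way up, and a final 1x1x1 convolution + sigmoid
producing a single foreground-probability channel.

Forward and backward passes are written directly in numpy (each 3x3x3
convolution is 27 shifted GEMMs), which keeps the engine dependency-free,
bitwise reproducible given a seed, and fast enough for desk-scale
training on 64^3 patches. Optimization is Adam (default learning rate
1e-4) on a combined objective

    L = lambda * dice + (1 - lambda) * focal,

where the focal term puts per-voxel weights of 0.75 on ROI and 0.25 on
non-ROI voxels to counter the small ROI volume.

Two trained instances form the cascade: model 1 segments the
tumor-bearing brain from the whole head, model 2 segments the tumor from
the brain-masked images; the predicted tumor is intersected with the
predicted brain, so contralateral tissue is available as brain - tumor.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import apply_ops, patchify, random_ops, unpatchify
from .volio import CaseRecord, Mask, ModalityStack

logger = logging.getLogger("rodentseg")

_P_EPS = 1e-7       # probability clipping for the focal term
_DICE_EPS = 1e-6    # dice smoothing constant


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    """Architecture hyperparameters (depth, width, patch size)."""

    in_channels: int = 3
    levels: int = 3
    base_filters: int = 8
    patch: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.patch % (2 ** self.levels):
            raise ValueError(
                f"patch {self.patch} must be divisible by 2^levels "
                f"= {2 ** self.levels}")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The defaults follow the training recipe: Adam with learning rate
    1e-4 and per-voxel class weights 0.75 (ROI) / 0.25 (background)
    inside the focal term. The dice/focal mixing weight, focal gamma,
    epoch and batch counts are unstated there and are exposed here with
    conventional defaults.
    """

    lr: float = 1e-4
    epochs: int = 15
    batch_size: int = 2
    w_roi: float = 0.75
    w_bg: float = 0.25
    dice_focal_mix: float = 0.5
    focal_gamma: float = 2.0
    augment: bool = True
    threshold: float = 0.5
    max_grad_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if abs(self.w_roi + self.w_bg - 1.0) > 1e-9:
            raise ValueError("w_roi + w_bg must equal 1")
        if not (0.0 <= self.dice_focal_mix <= 1.0):
            raise ValueError("dice_focal_mix must be in [0, 1]")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")


@dataclass
class ProbabilityMap:
    """Per-voxel foreground probabilities on the input lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    def binarize(self, role: str = "") -> Mask:
        return Mask((self.values >= self.threshold).astype(np.uint8),
                    self.spacing, role)


# ---------------------------------------------------------------------------
# Losses (values + analytic gradients w.r.t. the probabilities)
# ---------------------------------------------------------------------------

def _as_arrays(p, g):
    pv = p.values if isinstance(p, ProbabilityMap) else np.asarray(p)
    gv = g.labels if isinstance(g, Mask) else np.asarray(g)
    if pv.shape != gv.shape:
        raise ValueError(f"shape mismatch: {pv.shape} vs {gv.shape}")
    return pv.astype(np.float64), gv.astype(np.float64)


def dice_loss(p, g) -> float:
    """Soft dice loss 1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)."""
    pv, gv = _as_arrays(p, g)
    num = 2.0 * (pv * gv).sum() + _DICE_EPS
    den = pv.sum() + gv.sum() + _DICE_EPS
    return float(1.0 - num / den)


def _dice_grad(pv: np.ndarray, gv: np.ndarray) -> np.ndarray:
    num = 2.0 * (pv * gv).sum() + _DICE_EPS
    den = pv.sum() + gv.sum() + _DICE_EPS
    return (num / den ** 2 - 2.0 * gv / den)


def focal_loss(p, g, w_roi: float = 0.75, w_bg: float = 0.25,
               gamma: float = 2.0) -> float:
    """Class-weighted focal loss, mean over voxels.

    Per voxel: -w * (1 - p_t)^gamma * log(p_t), with p_t the predicted
    probability of the true class and w = w_roi on ROI voxels, w_bg on
    background voxels. gamma=0 reduces it to weighted cross-entropy.
    """
    pv, gv = _as_arrays(p, g)
    pv = np.clip(pv, _P_EPS, 1.0 - _P_EPS)
    pt = np.where(gv > 0.5, pv, 1.0 - pv)
    w = np.where(gv > 0.5, w_roi, w_bg)
    return float(np.mean(-w * (1.0 - pt) ** gamma * np.log(pt)))


def _focal_grad(pv: np.ndarray, gv: np.ndarray, w_roi: float, w_bg: float,
                gamma: float) -> np.ndarray:
    pv = np.clip(pv, _P_EPS, 1.0 - _P_EPS)
    n = pv.size
    roi = gv > 0.5
    grad = np.empty_like(pv)
    if gamma == 0.0:
        grad[roi] = -w_roi / pv[roi]
        grad[~roi] = w_bg / (1.0 - pv[~roi])
    else:
        p1 = pv[roi]
        grad[roi] = w_roi * (gamma * (1.0 - p1) ** (gamma - 1.0) * np.log(p1)
                             - (1.0 - p1) ** gamma / p1)
        p0 = pv[~roi]
        grad[~roi] = w_bg * (-gamma * p0 ** (gamma - 1.0) * np.log(1.0 - p0)
                             + p0 ** gamma / (1.0 - p0))
    return grad / n


def combined_loss(p, g, cfg: TrainConfig | None = None) -> float:
    """lambda * dice + (1 - lambda) * focal, lambda = cfg.dice_focal_mix."""
    cfg = cfg or TrainConfig()
    lam = cfg.dice_focal_mix
    return (lam * dice_loss(p, g)
            + (1.0 - lam) * focal_loss(p, g, cfg.w_roi, cfg.w_bg,
                                       cfg.focal_gamma))


def _combined_grad(pv: np.ndarray, gv: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    lam = cfg.dice_focal_mix
    grad = np.zeros_like(pv)
    if lam > 0:
        grad += lam * _dice_grad(pv, gv)
    if lam < 1:
        grad += (1.0 - lam) * _focal_grad(pv, gv, cfg.w_roi, cfg.w_bg,
                                          cfg.focal_gamma)
    return grad


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

_OFFSETS = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


class _Conv3(object):
    """3x3x3 same-padding convolution as 27 shifted GEMMs."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 27))
        self.W = rng.normal(0.0, std, size=(cout, cin, 3, 3, 3)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cin = x.shape[0]
        d, h, w = x.shape[1:]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        out = np.zeros((self.W.shape[0], d * h * w), dtype=np.float32)
        for dz, dy, dx in _OFFSETS:
            xs = xp[:, dz:dz + d, dy:dy + h, dx:dx + w].reshape(cin, -1)
            out += self.W[:, :, dz, dy, dx] @ xs
        out += self.b[:, None]
        self._xp = xp
        return out.reshape(-1, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        cin = xp.shape[0]
        d, h, w = dy.shape[1:]
        dyf = dy.reshape(dy.shape[0], -1).astype(np.float32)
        dxp = np.zeros_like(xp)
        for dz, dyo, dxo in _OFFSETS:
            xs = xp[:, dz:dz + d, dyo:dyo + h, dxo:dxo + w].reshape(cin, -1)
            self.gW[:, :, dz, dyo, dxo] += dyf @ xs.T
            dxp[:, dz:dz + d, dyo:dyo + h, dxo:dxo + w] += (
                self.W[:, :, dz, dyo, dxo].T @ dyf).reshape(cin, d, h, w)
        self.gb += dyf.sum(axis=1)
        self._xp = None
        return dxp[:, 1:-1, 1:-1, 1:-1]

    def params(self):
        return [("W", self), ("b", self)]


class _Conv1(object):
    """1x1x1 convolution (a per-voxel linear map)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias_init: float = 0.0):
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, std, size=(cout, cin)).astype(np.float32)
        self.b = np.full(cout, bias_init, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        shape = x.shape
        xf = x.reshape(shape[0], -1)
        out = self.W @ xf + self.b[:, None]
        self._x = xf
        return out.reshape(-1, *shape[1:])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyf = dy.reshape(dy.shape[0], -1).astype(np.float32)
        self.gW += dyf @ self._x.T
        self.gb += dyf.sum(axis=1)
        dx = self.W.T @ dyf
        shape = dy.shape[1:]
        self._x = None
        return dx.reshape(-1, *shape)


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _maxpool2_forward(x):
    c, d, h, w = x.shape
    xr = (x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
           .transpose(0, 1, 3, 5, 2, 4, 6)
           .reshape(c, d // 2, h // 2, w // 2, 8))
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool2_backward(dy, idx, in_shape):
    c, d, h, w = in_shape
    dxr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return (dxr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
               .transpose(0, 1, 4, 2, 5, 3, 6)
               .reshape(c, d, h, w))


def _upsample2_forward(x):
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(dy):
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class UNet3D:
    """Volumetric encoder-decoder with skip connections (see module doc).

    Channel widths double per level from ``base_filters``; input is a
    (3, d, h, w) array with d, h, w divisible by 2**levels.
    """

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        self.enc: list[tuple[_Conv3, _Conv3]] = []
        cin = cfg.in_channels
        widths = [f * 2 ** i for i in range(cfg.levels)]
        for wdt in widths:
            self.enc.append((_Conv3(cin, wdt, rng), _Conv3(wdt, wdt, rng)))
            cin = wdt
        bott = f * 2 ** cfg.levels
        self.bott = (_Conv3(cin, bott, rng), _Conv3(bott, bott, rng))
        self.dec: list[tuple[_Conv3, _Conv3]] = []
        cin = bott
        for wdt in reversed(widths):
            self.dec.append((_Conv3(cin + wdt, wdt, rng), _Conv3(wdt, wdt, rng)))
            cin = wdt
        # start near the background prior (sigmoid(-2) ~ 0.12 foreground):
        # a balanced start tames the focal term's first steps and avoids
        # early saturation of the output sigmoid
        self.head = _Conv1(cin, 1, rng, bias_init=-2.0)
        self._cache = None

    # -- parameter plumbing -------------------------------------------
    def _layers(self):
        for pair in self.enc:
            yield from pair
        yield from self.bott
        for pair in self.dec:
            yield from pair
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend([layer.W, layer.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend([layer.gW, layer.gb])
        return out

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward / backward -------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected ({self.cfg.in_channels}, d, h, w) input, got {x.shape}")
        div = 2 ** self.cfg.levels
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be divisible by {div}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Foreground probabilities, same spatial shape as the input."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        cache = {"relu": [], "pool": [], "skip_shapes": []}
        skips = []
        for conv_a, conv_b in self.enc:
            x, m1 = _relu_forward(conv_a.forward(x))
            x, m2 = _relu_forward(conv_b.forward(x))
            cache["relu"].append((m1, m2))
            skips.append(x)
            pooled, idx = _maxpool2_forward(x)
            cache["pool"].append((idx, x.shape))
            x = pooled
        x, mb1 = _relu_forward(self.bott[0].forward(x))
        x, mb2 = _relu_forward(self.bott[1].forward(x))
        cache["bott_relu"] = (mb1, mb2)
        cache["dec_relu"] = []
        cache["skip_channels"] = []
        for (conv_a, conv_b), skip in zip(self.dec, reversed(skips)):
            x = _upsample2_forward(x)
            cache["skip_channels"].append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x, m1 = _relu_forward(conv_a.forward(x))
            x, m2 = _relu_forward(conv_b.forward(x))
            cache["dec_relu"].append((m1, m2))
        logits = self.head.forward(x)[0]
        prob = expit(logits.astype(np.float64))
        if train:
            cache["prob"] = prob
            self._cache = cache
        else:
            self._cache = None
        return prob.astype(np.float32)

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients given dL/dprob."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward() requires forward(train=True)")
        prob = cache["prob"]
        dlogits = (dprob * prob * (1.0 - prob)).astype(np.float32)[None]
        dx = self.head.backward(dlogits)
        dskips = []  # collected shallowest-first (decoder runs in reverse)
        for (conv_a, conv_b), (m1, m2) in zip(reversed(self.dec),
                                              reversed(cache["dec_relu"])):
            dx = conv_b.backward(dx * m2)
            dx = conv_a.backward(dx * m1)
            # split the concat: the first nskip channels are the skip path
            nskip = cache["skip_channels"].pop()
            dskip, dup = dx[:nskip], dx[nskip:]
            dx = _upsample2_backward(dup)
            dskips.append(dskip)
        mb1, mb2 = cache["bott_relu"]
        dx = self.bott[1].backward(dx * mb2)
        dx = self.bott[0].backward(dx * mb1)
        for (conv_a, conv_b), (idx, shape), (m1, m2), dskip in zip(
                reversed(self.enc), reversed(cache["pool"]),
                reversed(cache["relu"]), reversed(dskips)):
            dx = _maxpool2_backward(dx, idx, shape)
            dx = dx + dskip
            dx = conv_b.backward(dx * m2)
            dx = conv_a.backward(dx * m1)
        self._cache = None


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _zscore_or_zero(chan: np.ndarray) -> np.ndarray:
    sd = chan.std()
    if sd == 0:
        return np.zeros_like(chan, dtype=np.float32)
    return ((chan - chan.mean()) / sd).astype(np.float32)


def network_input(stack: ModalityStack, brain_mask: Mask | None = None) -> np.ndarray:
    """Channel-wise z-scored (3, d, h, w) array; when a brain mask is
    given (stage-2 input), voxels outside the brain are zeroed after
    normalization."""
    arr = np.stack([_zscore_or_zero(v.data) for v in stack.volumes])
    if brain_mask is not None:
        arr = arr * brain_mask.labels.astype(np.float32)[None]
    return arr


def _iou(pred_bin: np.ndarray, g: np.ndarray) -> float:
    union = np.logical_or(pred_bin, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred_bin, g).sum() / union)


def split_indices(n: int, val_split: float, seed):
    """Seeded validation/training index split (val first, then train).

    ``seed`` may be an int or a Generator; train_model consumes the
    generator further for sample shuffling, so passing the same int here
    reproduces exactly the split train_model used.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_split * n)))
    if n_val >= n:
        raise ValueError("val_split leaves no training cases")
    return order[:n_val], order[n_val:]


def train_model(cases: list[CaseRecord], target: str, net_cfg: NetConfig,
                train_cfg: TrainConfig, val_split: float = 0.2):
    """Train one cascade stage; returns (network, trace DataFrame).

    ``target`` is "brain" (stage 1, whole-head input) or "tumor" (stage
    2, input masked to the ground-truth brain). The case split, sample
    order, augmentation draws and weight initialization all derive from
    the configured seeds, so two runs with identical inputs produce
    identical traces. The returned network carries the weights of the
    epoch with the best validation IoU.
    """
    if target not in ("brain", "tumor"):
        raise ValueError("target must be 'brain' or 'tumor'")
    if len(cases) < 2:
        raise ValueError("need at least 2 cases")
    for c in cases:
        mask = c.brain_mask if target == "brain" else c.tumor_mask
        if mask is None:
            raise ValueError(f"case {c.case_id} lacks a {target} mask")
    masks = [(c.brain_mask if target == "brain" else c.tumor_mask)
             for c in cases]
    if all(m.is_empty() for m in masks):
        raise ValueError(f"all {target} masks are empty")

    rng = np.random.default_rng(train_cfg.seed)
    val_idx, train_idx = split_indices(len(cases), val_split, rng)

    def samples_for(i: int):
        c = cases[i]
        x = network_input(c.stack, c.brain_mask if target == "tumor" else None)
        g = masks[i].labels
        grid_x = patchify(x, net_cfg.patch)
        grid_g = patchify(g[None], net_cfg.patch)
        return [(px, pg[0]) for px, pg in zip(grid_x.patches, grid_g.patches)]

    train_samples = [s for i in train_idx for s in samples_for(i)]
    val_samples = [s for i in val_idx for s in samples_for(i)]

    net = UNet3D(net_cfg)
    opt = _Adam(net.parameters(), train_cfg.lr)
    rows = []
    best_iou, best_state = -1.0, net.get_state()
    thr = train_cfg.threshold

    for epoch in range(1, train_cfg.epochs + 1):
        perm = rng.permutation(len(train_samples))
        ep_loss, ep_iou = [], []
        for start in range(0, len(perm), train_cfg.batch_size):
            batch = perm[start:start + train_cfg.batch_size]
            net.zero_grad()
            for j in batch:
                x, g = train_samples[j]
                if train_cfg.augment:
                    ops = random_ops(rng)
                    x = apply_ops(x, ops)
                    g = apply_ops(g, ops)
                p = net.forward(x, train=True)
                loss = combined_loss(p, g, train_cfg)
                grad = _combined_grad(np.clip(p.astype(np.float64), _P_EPS,
                                              1 - _P_EPS), g.astype(np.float64),
                                     train_cfg) / len(batch)
                net.backward(grad)
                ep_loss.append(loss)
                ep_iou.append(_iou(p >= thr, g > 0))
            grads = net.gradients()
            for gr in grads:
                if not np.all(np.isfinite(gr)):
                    raise FloatingPointError("non-finite gradient encountered")
            if train_cfg.max_grad_norm > 0:
                norm = float(np.sqrt(sum(float((g ** 2).sum()) for g in grads)))
                if norm > train_cfg.max_grad_norm:
                    scale = train_cfg.max_grad_norm / norm
                    for g in grads:
                        g *= scale
            opt.step(grads)
        rows.append({"epoch": epoch, "split": "train",
                     "loss": float(np.mean(ep_loss)),
                     "iou": float(np.mean(ep_iou))})

        v_loss, v_iou = [], []
        for x, g in val_samples:
            p = net.forward(x)
            v_loss.append(combined_loss(p, g, train_cfg))
            v_iou.append(_iou(p >= thr, g > 0))
        miou = float(np.mean(v_iou))
        rows.append({"epoch": epoch, "split": "val",
                     "loss": float(np.mean(v_loss)), "iou": miou})
        logger.info("[%s] epoch %d train loss %.4f val IoU %.4f",
                    target, epoch, rows[-2]["loss"], miou)
        if miou > best_iou:
            best_iou, best_state = miou, net.get_state()

    net.set_state(best_state)
    return net, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(net: UNet3D, s: ModalityStack | np.ndarray,
            patch: int | None = None) -> ProbabilityMap:
    """Tiled forward pass over non-overlapping patches, reassembled to
    the full grid. ``s`` may be a ModalityStack (z-scored internally) or
    an already-normalized (3, d, h, w) array."""
    patch = patch or net.cfg.patch
    if isinstance(s, ModalityStack):
        arr, spacing = network_input(s), s.spacing
    else:
        arr, spacing = np.asarray(s, dtype=np.float32), (1.0, 1.0, 1.0)
    grid = patchify(arr, patch)
    out_patches = [net.forward(px)[None] for px in grid.patches]
    prob = unpatchify(PatchGridLike(grid, out_patches))[0]
    return ProbabilityMap(values=np.clip(prob, 0.0, 1.0), spacing=spacing)


class PatchGridLike:
    """A PatchGrid view with substituted patch payloads (same tiling)."""

    def __init__(self, grid, patches):
        self.patches = patches
        self.origins = grid.origins
        self.source_shape = grid.source_shape
        self.patch = grid.patch


def segment_stepwise(net1: UNet3D, net2: UNet3D, s: ModalityStack,
                     threshold: float = 0.5, patch: int | None = None):
    """Run the two-stage cascade on a preprocessed stack.

    Stage 1 thresholds the whole-head probability map into the brain
    mask; stage 2 re-runs on the stack with voxels outside that brain
    zeroed, and its thresholded output is intersected with the brain, so
    tumor ⊆ brain always. An empty brain prediction yields an empty
    tumor with a warning.
    """
    x = network_input(s)
    p1 = predict(net1, x, patch or net1.cfg.patch)
    brain = Mask((p1.values >= threshold).astype(np.uint8), s.spacing, "brain")
    if brain.is_empty():
        warnings.warn("stage 1 predicted an empty brain; tumor left empty")
        tumor = Mask(np.zeros_like(brain.labels), s.spacing, "tumor")
        return brain, tumor
    x2 = x * brain.labels.astype(np.float32)[None]
    p2 = predict(net2, x2, patch or net2.cfg.patch)
    tumor_lbl = ((p2.values >= threshold) & brain.as_bool()).astype(np.uint8)
    return brain, Mask(tumor_lbl, s.spacing, "tumor")


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: UNet3D, path: str | Path,
                    train_cfg: TrainConfig | None = None) -> Path:
    """Native .npz checkpoint with the NetConfig/TrainConfig embedded as JSON."""
    path = Path(path)
    meta = {"net": asdict(net.cfg)}
    if train_cfg is not None:
        meta["train"] = asdict(train_cfg)
    arrays = {f"p{i:03d}": p for i, p in enumerate(net.parameters())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path: str | Path) -> UNet3D:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        net = UNet3D(NetConfig(**meta["net"]))
        state = [data[f"p{i:03d}"] for i in range(len(net.parameters()))]
    net.set_state(state)
    return net
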