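"""Sinogram-completion network: encoder–decoder with skip connections,
trained under a masked-L2 + continuity + consistency composite loss.

Architecture
------------
A U-net variant for single-channel sinograms.  Each encoder block applies two
3x3 stride-1 convolutions (leaky rectifier, negative slope 0.2) and reduces
resolution with a 3x3 stride-2 convolution in place of pooling; the channel
schedule is ``base, 2*base, 4*base`` and then ``8*base`` repeated.  Each
decoder block upsamples with a stride-2 transposed convolution (implemented
as zero-stuffing followed by a 3x3 convolution, which is the standard
parameterization of a stride-2 deconvolution), concatenates the matching
encoder feature map, and applies two 3x3 convolutions with plain rectifiers.
A final linear 3x3 convolution maps back to one channel, so the output has
the input's shape.

Loss
----
With ``f`` the network output, ``fhat`` the label sinogram, and ``M`` the
binary trace mask (1 on metal-damaged entries), the training objective is

    L2loss   = sum_{x,theta} ( M*f - M*fhat )^2          (trace-restricted)
    Amploss  = sum_{x,theta} ( D_x f - D_x fhat )^2      (detector-axis first
                                                          differences: edge
                                                          continuity)
    Diffloss = sum_theta ( sum_x f - sum_x fhat )^2      (per-angle projection
                                                          mass: order-0
                                                          consistency)
    Loss     = w_l2*L2loss + w_amp*Amploss + w_diff*Diffloss

with unit weights by default.  Amploss and Diffloss are deliberately
unmasked: they constrain the whole output, pulling the filled trace toward
values that join continuously at the trace edges and restore the
angle-independent projection mass that trace zeroing destroyed.

Everything here is NumPy: forward passes, analytic backward passes, and Adam.
All tensors are float32 NHWC (batch, detector, angle, channel).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .projection import Sinogram
from .traces import SinogramPair, TraceMask, composite

__all__ = [
    "NetConfig",
    "TrainConfig",
    "LossReport",
    "PadRecord",
    "loss_l2",
    "loss_amp",
    "loss_diff",
    "total_loss",
    "total_loss_grad",
    "build_unet",
    "UNet",
    "pad_for_net",
    "crop_from_net",
    "train",
    "complete",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``depth`` counts down/up-sampling stages; the padded input side must be
    divisible by ``2**depth``.  Full scale is depth 5 / base 64 (bottleneck
    1/32 of the input side); ``desk()`` gives the small CPU-friendly variant.
    """

    depth: int = 5
    base_channels: int = 64
    encoder_negative_slope: float = 0.2

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @classmethod
    def desk(cls) -> "NetConfig":
        return cls(depth=4, base_channels=16)

    @property
    def channel_schedule(self) -> tuple[int, ...]:
        return tuple(self.base_channels * min(2 ** i, 8)
                     for i in range(self.depth))

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * min(2 ** self.depth, 8)


@dataclass
class TrainConfig:
    """Training hyperparameters and ablation switches.

    ``use_mask`` restricts the L2 term to the trace (the proposed method);
    switching it off reproduces a plain globally-supervised net.  ``use_amp``
    and ``use_diff`` toggle the two sinogram feature losses.  Unit loss
    weights reproduce the plain three-term sum.
    """

    steps: int = 500
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    w_l2: float = 1.0
    w_amp: float = 1.0
    w_diff: float = 1.0
    use_mask: bool = True
    use_amp: bool = True
    use_diff: bool = True
    val_every: int = 50
    checkpoint_path: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.steps < 1 or self.batch_size < 1:
            raise ValueError("steps and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if min(self.w_l2, self.w_amp, self.w_diff) < 0:
            raise ValueError("loss weights must be >= 0")

    def effective_weights(self) -> tuple[float, float, float]:
        return (self.w_l2,
                self.w_amp if self.use_amp else 0.0,
                self.w_diff if self.use_diff else 0.0)


@dataclass(frozen=True)
class LossReport:
    """The three loss terms and their weighted total."""

    l2: float
    amp: float
    diff: float
    total: float


# ---------------------------------------------------------------------------
# Losses (array in, scalar out, with analytic gradients)
#
# Arrays are (detector, angle) or batched (..., detector, angle): the detector
# axis is -2, the angle axis -1.

def _check_shapes(output: np.ndarray, label: np.ndarray) -> None:
    if output.shape != label.shape:
        raise ValueError(f"shape mismatch: output {output.shape} vs label "
                         f"{label.shape}")


def loss_l2(output: np.ndarray, label: np.ndarray, mask: np.ndarray) -> float:
    """Trace-restricted squared error: sum over entries of (M f - M fhat)^2.
    Only mask-1 entries contribute."""
    output, label = np.asarray(output), np.asarray(label)
    mask = np.asarray(mask)
    _check_shapes(output, label)
    if mask.shape != output.shape:
        raise ValueError(f"mask shape {mask.shape} does not match "
                         f"{output.shape}")
    d = mask * (output - label)
    return float((d * d).sum())


def loss_amp(output: np.ndarray, label: np.ndarray) -> float:
    """Continuity (amplitude) loss: squared mismatch of first differences
    along the detector axis."""
    output, label = np.asarray(output), np.asarray(label)
    _check_shapes(output, label)
    if output.shape[-2] < 2:
        raise ValueError("amplitude loss needs at least 2 detector bins")
    r = np.diff(output, axis=-2) - np.diff(label, axis=-2)
    return float((r * r).sum())


def loss_diff(output: np.ndarray, label: np.ndarray) -> float:
    """Consistency (difference) loss: squared mismatch of per-angle detector
    sums — the discrete order-0 projection moment."""
    output, label = np.asarray(output), np.asarray(label)
    _check_shapes(output, label)
    c = output.sum(axis=-2) - label.sum(axis=-2)
    return float((c * c).sum())


def total_loss(output: np.ndarray, label: np.ndarray, mask: np.ndarray,
               weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
               ) -> LossReport:
    """Composite objective; unit weights give the plain three-term sum."""
    w_l2, w_amp, w_diff = weights
    if min(weights) < 0:
        raise ValueError("loss weights must be >= 0")
    l2 = loss_l2(output, label, mask)
    amp = loss_amp(output, label)
    diff = loss_diff(output, label)
    return LossReport(l2, amp, diff,
                      w_l2 * l2 + w_amp * amp + w_diff * diff)


def total_loss_grad(output: np.ndarray, label: np.ndarray, mask: np.ndarray,
                    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
                    ) -> np.ndarray:
    """Analytic gradient of the composite loss w.r.t. the network output."""
    output = np.asarray(output, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    mask = np.asarray(mask)
    w_l2, w_amp, w_diff = weights
    if min(weights) < 0:
        raise ValueError("loss weights must be >= 0")
    grad = np.zeros_like(output)
    # L2: d/df sum (M(f-fhat))^2 = 2 M (f - fhat)   (M binary)
    grad += w_l2 * 2.0 * mask * (output - label)
    # Amp: r = D(f - fhat); d/df sum r^2 = 2 D^T r  (adjoint of first diff)
    r = np.diff(output, axis=-2) - np.diff(label, axis=-2)
    dt = np.zeros_like(output)
    sl_lo = (Ellipsis, slice(None, -1), slice(None))
    sl_hi = (Ellipsis, slice(1, None), slice(None))
    dt[sl_lo] -= r
    dt[sl_hi] += r
    grad += w_amp * 2.0 * dt
    # Diff: c = colsum(f - fhat); d/df sum c^2 = 2 c broadcast over detectors
    c = output.sum(axis=-2) - label.sum(axis=-2)
    grad += w_diff * 2.0 * np.expand_dims(c, -2)
    return grad


# ---------------------------------------------------------------------------
# Layers (float32 NHWC, explicit backward passes)

class _Conv2d:
    """3x3 convolution, stride 1 or 2, zero padding 1.

    Implemented as nine shifted matmuls over strided views; the flattened
    views are cached for the weight-gradient pass.
    """

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / (9 * c_in))
        self.W = rng.normal(0.0, std, size=(3, 3, c_in, c_out)
                            ).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.stride = stride
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, ci = x.shape
        s = self.stride
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        ho = (h - 1) // s + 1
        wo = (w - 1) // s + 1
        co = self.W.shape[3]
        out = np.empty((n * ho * wo, co), dtype=x.dtype)
        out[:] = self.b
        views = []
        for dy in range(3):
            for dx in range(3):
                v = np.ascontiguousarray(
                    xp[:, dy:dy + s * (ho - 1) + 1:s,
                       dx:dx + s * (wo - 1) + 1:s, :]).reshape(-1, ci)
                out += v @ self.W[dy, dx]
                views.append(v)
        self._cache = (views, (n, h, w, ci), (ho, wo), xp.shape)
        return out.reshape(n, ho, wo, co)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        views, (n, h, w, ci), (ho, wo), xp_shape = self._cache
        s = self.stride
        co = self.W.shape[3]
        g = dout.reshape(-1, co)
        self.db = g.sum(axis=0)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for k, (dy, dx) in enumerate((dy, dx) for dy in range(3)
                                     for dx in range(3)):
            sly = slice(dy, dy + s * (ho - 1) + 1, s)
            slx = slice(dx, dx + s * (wo - 1) + 1, s)
            self.dW[dy, dx] = views[k].T @ g
            dxp[:, sly, slx, :] += (g @ self.W[dy, dx].T
                                    ).reshape(n, ho, wo, ci)
        self._cache = None
        return dxp[:, 1:1 + h, 1:1 + w, :]

    def params(self):
        return [(self, "W"), (self, "b")]


# index map for the stride-2 transposed conv: output rows with parity set by
# the kernel row dy receive input rows in_lo..h-1 (see _ConvTranspose2d)
_TC_SLICES = {0: (1, 0), 1: (0, 0), 2: (1, 1)}


class _ConvTranspose2d:
    """3x3 transposed convolution, stride 2 (output side = 2 * input side).

    Equivalent to zero-stuffing the input on a doubled grid and applying a
    3x3 stride-1 convolution with unit padding, but computed directly at the
    low resolution: each kernel tap only ever meets one output parity class,
    so the nine taps are nine low-resolution matmuls.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / (9 * c_in))
        self.W = rng.normal(0.0, std, size=(3, 3, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @staticmethod
    def _slices(d: int, size: int) -> tuple[slice, slice]:
        # output index u = 2a + 1 - d for input index a: valid a start and
        # the output parity offset
        off, a_lo = _TC_SLICES[d]
        u_lo = 2 * a_lo + 1 - d
        n_terms = size - a_lo
        return (slice(u_lo, u_lo + 2 * (n_terms - 1) + 1, 2),
                slice(a_lo, size))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, ci = x.shape
        co = self.W.shape[3]
        out = np.empty((n, 2 * h, 2 * w, co), dtype=x.dtype)
        out[:] = self.b
        for dy in range(3):
            uy, ay = self._slices(dy, h)
            for dx in range(3):
                ux, ax = self._slices(dx, w)
                v = x[:, ay, ax, :]
                out[:, uy, ux, :] += (v.reshape(-1, ci) @ self.W[dy, dx]
                                      ).reshape(v.shape[:3] + (co,))
        self._cache = (x, (n, h, w, ci))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, (n, h, w, ci) = self._cache
        co = self.W.shape[3]
        self.db = dout.reshape(-1, co).sum(axis=0)
        dx_in = np.zeros_like(x)
        for dy in range(3):
            uy, ay = self._slices(dy, h)
            for dx in range(3):
                ux, ax = self._slices(dx, w)
                g = np.ascontiguousarray(dout[:, uy, ux, :]).reshape(-1, co)
                v = np.ascontiguousarray(x[:, ay, ax, :]).reshape(-1, ci)
                self.dW[dy, dx] = v.T @ g
                dx_in[:, ay, ax, :] += (g @ self.W[dy, dx].T
                                        ).reshape(n, len(range(h)[ay]),
                                                  len(range(w)[ax]), ci)
        self._cache = None
        return dx_in

    def params(self):
        return [(self, "W"), (self, "b")]


class _Rectifier:
    """Leaky (or plain, slope=0) rectifier.

    Operates in place on the incoming activation/gradient, which the
    preceding convolution owns exclusively.
    """

    def __init__(self, negative_slope: float = 0.0):
        self.slope = negative_slope
        self._neg = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        if self.slope:
            x[self._neg] *= np.asarray(self.slope, dtype=x.dtype)
        else:
            x[self._neg] = 0
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.slope:
            dout[self._neg] *= np.asarray(self.slope, dtype=dout.dtype)
        else:
            dout[self._neg] = 0
        self._neg = None
        return dout

    def params(self):
        return []


class UNet:
    """Encoder–decoder completion network (see module docstring).

    Construction is deterministic for a fixed seed; two builds with the same
    seed have identical initial parameters.  ``scale`` is the normalization
    factor recorded at training time (inputs are divided by it and outputs
    multiplied back); it is ``None`` until training or checkpoint loading
    sets it.
    """

    def __init__(self, config: NetConfig, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self.scale: float | None = None
        rng = np.random.default_rng(seed)
        sched = config.channel_schedule
        slope = config.encoder_negative_slope

        self.enc: list[dict] = []
        c_in = 1
        for i in range(config.depth):
            c = sched[i]
            c_next = sched[i + 1] if i + 1 < config.depth \
                else config.bottleneck_channels
            self.enc.append({
                "conv1": _Conv2d(c_in, c, 1, rng, self.dtype),
                "act1": _Rectifier(slope),
                "conv2": _Conv2d(c, c, 1, rng, self.dtype),
                "act2": _Rectifier(slope),
                "down": _Conv2d(c, c_next, 2, rng, self.dtype),
                "dact": _Rectifier(slope),
            })
            c_in = c_next

        cb = config.bottleneck_channels
        self.bott = {
            "conv1": _Conv2d(cb, cb, 1, rng, self.dtype),
            "act1": _Rectifier(slope),
            "conv2": _Conv2d(cb, cb, 1, rng, self.dtype),
            "act2": _Rectifier(slope),
        }

        self.dec: list[dict] = []
        c_in = cb
        for i in reversed(range(config.depth)):
            c = sched[i]
            self.dec.append({
                "upconv": _ConvTranspose2d(c_in, c, rng, self.dtype),
                "upact": _Rectifier(0.0),
                "conv1": _Conv2d(2 * c, c, 1, rng, self.dtype),
                "act1": _Rectifier(0.0),
                "conv2": _Conv2d(c, c, 1, rng, self.dtype),
                "act2": _Rectifier(0.0),
            })
            c_in = c
        self.out_conv = _Conv2d(sched[0], 1, 1, rng, self.dtype)
        self._skip_channels: list[int] = []

    # -- plumbing -----------------------------------------------------------

    def parameters(self):
        handles = []
        for blk in self.enc + [self.bott] + self.dec:
            for layer in blk.values():
                handles.extend(layer.params())
        handles.extend(self.out_conv.params())
        return handles

    def _check_input(self, x: np.ndarray) -> None:
        n, h, w, c = x.shape
        div = 2 ** self.config.depth
        if h % div or w % div:
            need_h = (-h) % div
            need_w = (-w) % div
            raise ValueError(
                f"input side(s) ({h}, {w}) not divisible by 2^depth={div}; "
                f"pad by ({need_h}, {need_w}) (see pad_for_net)")
        if c != 1:
            raise ValueError(f"expected 1 input channel, got {c}")

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a float32 (N, H, W, 1) batch to an equal-shaped output."""
        x = np.asarray(x, dtype=self.dtype)
        self._check_input(x)
        skips = []
        for blk in self.enc:
            x = blk["act1"].forward(blk["conv1"].forward(x))
            x = blk["act2"].forward(blk["conv2"].forward(x))
            skips.append(x)
            x = blk["dact"].forward(blk["down"].forward(x))
        x = self.bott["act1"].forward(self.bott["conv1"].forward(x))
        x = self.bott["act2"].forward(self.bott["conv2"].forward(x))
        for blk, skip in zip(self.dec, reversed(skips)):
            x = blk["upact"].forward(blk["upconv"].forward(x))
            x = np.concatenate([skip, x], axis=-1)
            x = blk["act1"].forward(blk["conv1"].forward(x))
            x = blk["act2"].forward(blk["conv2"].forward(x))
        self._skip_channels = [s.shape[-1] for s in skips]
        return self.out_conv.forward(x)

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients for the last forward pass."""
        g = self.out_conv.backward(np.asarray(dout, dtype=self.dtype))
        # decoder blocks are stored deepest-first; traverse shallowest-first,
        # whose skip comes from the shallowest encoder level
        skip_grads: list[np.ndarray] = []
        for blk, c_skip in zip(reversed(self.dec), self._skip_channels):
            g = blk["conv2"].backward(blk["act2"].backward(g))
            g = blk["conv1"].backward(blk["act1"].backward(g))
            skip_grads.append(g[..., :c_skip])
            g = g[..., c_skip:]
            g = blk["upconv"].backward(blk["upact"].backward(g))
        g = self.bott["conv2"].backward(self.bott["act2"].backward(g))
        g = self.bott["conv1"].backward(self.bott["act1"].backward(g))
        for blk, sg in zip(reversed(self.enc), reversed(skip_grads)):
            g = blk["down"].backward(blk["dact"].backward(g))
            g = g + sg
            g = blk["conv2"].backward(blk["act2"].backward(g))
            g = blk["conv1"].backward(blk["act1"].backward(g))


def build_unet(config: NetConfig, seed: int = 0) -> UNet:
    """Construct the completion network; deterministic for a fixed seed."""
    return UNet(config, seed=seed)


# ---------------------------------------------------------------------------
# Padding: sinograms to network-divisible sizes and back

@dataclass(frozen=True)
class PadRecord:
    """Exact inverse record for pad_for_net."""

    orig_shape: tuple[int, int]
    det_pad: tuple[int, int]      # symmetric zero pad on the detector axis
    ang_pad: int                  # circular pad appended on the angle axis


def pad_for_net(values: np.ndarray, depth: int
                ) -> tuple[np.ndarray, PadRecord]:
    """Pad a (detector, angle) array up to the next multiple of 2**depth.

    The detector axis is zero-padded symmetrically (physically zero outside
    the detector support); the angle axis is padded circularly at the end
    (a full-scan sinogram is periodic in the angle), so padded column
    ``n_angles + j`` equals column ``j``.
    """
    values = np.asarray(values)
    h, w = values.shape
    div = 2 ** depth
    ht = ((h + div - 1) // div) * div
    wt = ((w + div - 1) // div) * div
    lo = (ht - h) // 2
    hi = ht - h - lo
    ang = wt - w
    if ang > w:
        raise ValueError("angle axis shorter than the required circular pad; "
                         "reduce depth or supply more angles")
    out = np.pad(values, ((lo, hi), (0, 0)))
    if ang:
        out = np.concatenate([out, out[:, :ang]], axis=1)
    return out, PadRecord((h, w), (lo, hi), ang)


def crop_from_net(values: np.ndarray, record: PadRecord) -> np.ndarray:
    """Invert pad_for_net bit-exactly."""
    h, w = record.orig_shape
    lo, _ = record.det_pad
    return values[lo:lo + h, :w]


# ---------------------------------------------------------------------------
# Optimization

class _Adam:
    def __init__(self, handles, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.handles = handles
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(o, n)) for o, n in handles]
        self.v = [np.zeros_like(getattr(o, n)) for o, n in handles]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (obj, name) in enumerate(self.handles):
            g = getattr(obj, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p = getattr(obj, name)
            p -= self.lr * (self.m[i] / b1t) / \
                (np.sqrt(self.v[i] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training and inference

def _stack_padded(pairs: list[SinogramPair], depth: int, scale: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, PadRecord]:
    xs, ys, ms = [], [], []
    rec = None
    for p in pairs:
        x, rec = pad_for_net(p.corrupted.values / scale, depth)
        y, _ = pad_for_net(p.label.values / scale, depth)
        m, _ = pad_for_net(p.mask.values, depth)
        xs.append(x)
        ys.append(y)
        ms.append(m)
    x = np.stack(xs).astype(np.float32)[..., None]
    y = np.stack(ys).astype(np.float32)[..., None]
    m = np.stack(ms).astype(np.float32)[..., None]
    return x, y, m, rec


def train(pairs: list[SinogramPair], net_config: NetConfig,
          train_config: TrainConfig,
          val_pairs: list[SinogramPair] | None = None
          ) -> tuple[UNet, list[dict]]:
    """Train the completion network on sinogram pairs.

    Inputs are normalized by the maximum label value of the training set
    (recorded on the model as ``scale``).  The loss is evaluated on the
    original (cropped) sinogram region, so padding never contributes
    supervision.  Returns the trained model and a per-step history of loss
    terms (plus periodic held-out trace-region MAE when ``val_pairs`` is
    given).  Raises on a non-finite loss.
    """
    if not pairs:
        raise ValueError("empty training set")
    if train_config.optimizer.lower() != "adam":
        raise ValueError(f"unknown optimizer {train_config.optimizer!r}")
    scale = max(float(p.label.values.max()) for p in pairs)
    if scale <= 0:
        scale = 1.0

    depth = net_config.depth
    x_all, y_all, m_all, rec = _stack_padded(pairs, depth, scale)
    n = x_all.shape[0]
    h0, w0 = rec.orig_shape
    lo = rec.det_pad[0]
    crop = (slice(None), slice(lo, lo + h0), slice(None, w0), slice(None))

    model = build_unet(net_config, seed=train_config.seed)
    model.scale = scale
    opt = _Adam(model.parameters(), train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    weights = train_config.effective_weights()

    history: list[dict] = []
    for step in range(1, train_config.steps + 1):
        idx = rng.choice(n, size=min(train_config.batch_size, n),
                         replace=n < train_config.batch_size)
        xb, yb, mb = x_all[idx], y_all[idx], m_all[idx]
        out = model.forward(xb)
        oc, yc = out[crop], yb[crop]
        mc = mb[crop] if train_config.use_mask else np.ones_like(yc)
        # losses/grad on (N, det, angle): drop the channel axis
        report = total_loss(oc[..., 0], yc[..., 0], mc[..., 0], weights)
        if not np.isfinite(report.total):
            raise RuntimeError(
                f"training diverged at step {step}: loss={report.total!r} "
                f"(l2={report.l2!r}, amp={report.amp!r}, diff={report.diff!r})")
        g = total_loss_grad(oc[..., 0], yc[..., 0], mc[..., 0], weights)
        dout = np.zeros_like(out)
        dout[crop] = g[..., None].astype(np.float32)
        model.backward(dout)
        opt.step()

        entry = {"step": step, "l2": report.l2, "amp": report.amp,
                 "diff": report.diff, "total": report.total}
        if val_pairs and (step % train_config.val_every == 0
                          or step == train_config.steps):
            entry["val_trace_mae"] = validation_trace_mae(model, val_pairs)
        history.append(entry)

    if train_config.log_path:
        _write_log(history, train_config.log_path)
    if train_config.checkpoint_path:
        save_checkpoint(model, train_config.checkpoint_path,
                        train_config=train_config)
    return model, history


def validation_trace_mae(model: UNet, pairs: list[SinogramPair]) -> float:
    """Mean trace-region MAE of completed sinograms over held-out pairs."""
    total, count = 0.0, 0
    for p in pairs:
        m = p.mask.values.astype(bool)
        if not m.any():
            continue
        done = complete(p.corrupted, p.mask, model)
        total += np.abs(done.values[m] - p.label.values[m]).sum()
        count += int(m.sum())
    if count == 0:
        raise ValueError("validation pairs contain no trace entries")
    return total / count


def complete(sino: Sinogram, mask: TraceMask, model: UNet) -> Sinogram:
    """Complete a corrupted sinogram with the trained network.

    Normalizes by the training scale, pads to a network-divisible size,
    runs the forward pass, crops, un-normalizes, and composites with the
    original so every mask-0 entry is the bit-exact input value.
    """
    if model.scale is None:
        raise ValueError("model has no normalization scale; train it or load "
                         "a checkpoint first")
    x, rec = pad_for_net(sino.values / model.scale, model.config.depth)
    out = model.forward(x.astype(np.float32)[None, ..., None])
    filled = crop_from_net(out[0, ..., 0].astype(np.float64), rec) \
        * model.scale
    if not np.all(np.isfinite(filled)):
        raise RuntimeError("network produced non-finite values")
    completed = Sinogram(filled, sino.geometry, scale=sino.scale)
    return composite(completed, sino, mask)


# ---------------------------------------------------------------------------
# Checkpointing and logs

def save_checkpoint(model: UNet, path: str | Path,
                    train_config: TrainConfig | None = None) -> None:
    """Weights as NPZ plus a JSON metadata sidecar (config, scale, seed)."""
    path = Path(path)
    arrays = {f"p{i}": getattr(obj, name)
              for i, (obj, name) in enumerate(model.parameters())}
    np.savez(path, **arrays)
    meta = {
        "net_config": asdict(model.config),
        "seed": model.seed,
        "scale": model.scale,
    }
    if train_config is not None:
        meta["train_config"] = asdict(train_config)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    model = UNet(NetConfig(**meta["net_config"]), seed=meta["seed"])
    model.scale = meta["scale"]
    data = np.load(path)
    for i, (obj, name) in enumerate(model.parameters()):
        arr = data[f"p{i}"]
        if arr.shape != getattr(obj, name).shape:
            raise ValueError("checkpoint does not match the network config")
        setattr(obj, name, arr.astype(np.float32))
    return model


def _write_log(history: list[dict], path: str | Path) -> None:
    keys = ["step", "l2", "amp", "diff", "total", "val_trace_mae"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        for entry in history:
            writer.writerow({k: entry.get(k, "") for k in keys})
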