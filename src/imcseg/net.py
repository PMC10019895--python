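"""U-Net semantic segmentation: model, loss, training loop, inference.

The network follows the classic U-shaped encoder/decoder: each contracting
block applies two 3x3 convolutions with ReLU and a 2x2 max-pool, doubling the
filter count; the expansive path mirrors it with 2x2 up-convolutions and skip
concatenations, and a final 1x1 convolution with logistic activation yields a
per-pixel cell probability. Convolutions use same-padding so the output mask
has exactly the input's spatial size — necessary because predictions on
128x128 tiles are reassembled into the full image.

Training minimizes per-pixel binary cross-entropy with Adam (batch size 16 by
default), stopping early when the validation loss stops improving. The whole
stack — forward, backward, optimizer — is implemented in NumPy (float32, with
convolutions lowered to a single BLAS GEMM via im2col), so it runs anywhere
and is exactly reproducible from a seed on a given machine.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from imcseg.compositing import CompositeImage
from imcseg.patching import DEFAULT_PATCH_SIZE, merge_patches, split_patches

__all__ = [
    "NetConfig",
    "TrainingExample",
    "UNet",
    "bce_loss",
    "binarize",
    "train",
    "predict",
]

_EPS = 1e-7  # probability clamp inside the loss, avoids log(0)


@dataclass
class NetConfig:
    """Architecture and training hyperparameters.

    ``depth`` counts contracting blocks; ``base_filters`` is the channel width
    of the first block (doubling per level, classic U-Net uses 64; 16 is a
    CPU-friendly profile). Adam runs at its standard settings. Early stopping
    monitors validation loss and restores the best weights.
    """

    depth: int = 4
    base_filters: int = 64
    batch_size: int = 16
    max_epochs: int = 500
    early_stop_patience: int = 20
    validation_fraction: float = 0.1
    learning_rate: float = 1e-3
    patch_size: int = DEFAULT_PATCH_SIZE
    in_channels: int = 2
    augment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patch_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} must be divisible by 2^depth = {2 ** self.depth}"
            )


@dataclass
class TrainingExample:
    """One supervised patch: (2, S, S) composite planes and an (S, S) 0/1 target."""

    patch: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.float32)
        self.target = np.asarray(self.target)
        if self.patch.ndim != 3 or self.patch.shape[0] != 2:
            raise ValueError(f"patch must be (2, S, S), got {self.patch.shape}")
        if self.target.shape != self.patch.shape[1:]:
            raise ValueError(
                f"target shape {self.target.shape} does not match patch {self.patch.shape[1:]}"
            )
        vals = np.unique(self.target)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("target must be binary (0 = background, 1 = cell)")
        self.target = self.target.astype(np.float32)


# ---------------------------------------------------------------------------
# Loss and binarization


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Per-pixel binary cross-entropy, averaged over all N pixels.

    ``-(1/N) * sum_i [ y_i * ln(yhat_i) + (1 - y_i) * ln(1 - yhat_i) ]`` with
    natural logarithm; predictions are clamped to ``[1e-7, 1 - 1e-7]`` before
    the logs so perfect-confidence predictions stay finite.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: target {y.shape} vs prediction {y_hat.shape}")
    if y.size == 0:
        raise ValueError("empty arrays")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("target values must be 0 or 1")
    yh = np.clip(y_hat, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(yh) + (1.0 - y) * np.log1p(-yh)))


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a 0/1 mask (1 = cell, 0 = background).

    Pixels below the threshold become 0, pixels at or above it become 1; the
    tie at exactly the threshold goes to foreground.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    prob = np.asarray(prob)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (prob >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# Layer primitives (NHWC). A 3x3 same-padding convolution is computed as nine
# batched matmuls on shifted views of the padded input — one per kernel
# offset — which keeps memory traffic far below an explicit im2col buffer.
# The weight for a conv is stored flat as (9 * Cin, Cout), offset-major.

_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]


def _conv3x3_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    wk = w.reshape(9, c, -1)
    y = np.matmul(xp[:, 0:h, 0:wd, :], wk[0])
    tmp = np.empty_like(y)
    for k in range(1, 9):
        di, dj = _OFFSETS[k]
        np.matmul(xp[:, di:di + h, dj:dj + wd, :], wk[k], out=tmp)
        y += tmp
    y += b
    return y, xp


def _conv3x3_bwd(dy: np.ndarray, xp: np.ndarray, w: np.ndarray):
    n, h, wd, cout = dy.shape
    c = xp.shape[-1]
    wk = w.reshape(9, c, cout)
    dw = np.empty((9, c, cout), dtype=w.dtype)
    dxp = np.zeros_like(xp)
    tmp = np.empty((n, h, wd, c), dtype=xp.dtype)
    for k, (di, dj) in enumerate(_OFFSETS):
        xs = xp[:, di:di + h, dj:dj + wd, :]
        # dW_k = sum over batch and positions of x^T dy, as batched matmul
        dw[k] = np.matmul(xs.swapaxes(-1, -2), dy).sum(axis=(0, 1))
        np.matmul(dy, wk[k].swapaxes(0, 1), out=tmp)
        dxp[:, di:di + h, dj:dj + wd, :] += tmp
    db = dy.reshape(-1, cout).sum(axis=0)
    return dxp[:, 1:-1, 1:-1, :], dw.reshape(9 * c, cout), db


def _maxpool_fwd(x: np.ndarray):
    # max over each 2x2 block via four strided views; x and y are cached so
    # the backward pass can recover the winning positions without an argmax
    y = np.maximum(
        np.maximum(x[:, 0::2, 0::2], x[:, 0::2, 1::2]),
        np.maximum(x[:, 1::2, 0::2], x[:, 1::2, 1::2]),
    )
    return y, (x, y)


def _maxpool_bwd(dy: np.ndarray, pool_cache) -> np.ndarray:
    x, y = pool_cache
    dx = np.zeros_like(x)
    remaining = np.ones(dy.shape, dtype=bool)
    zero = np.zeros((), dtype=dy.dtype)
    for si in (0, 1):
        for sj in (0, 1):
            xs = x[:, si::2, sj::2]
            take = remaining & (xs == y)
            dx[:, si::2, sj::2] = np.where(take, dy, zero)
            remaining &= ~take
    return dx


def _upconv_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    # 2x2 transposed convolution, stride 2: each input pixel emits a 2x2 block
    n, h, wd, c = x.shape
    cout = w.shape[1] // 4
    t = (x.reshape(-1, c) @ w).reshape(n, h, wd, 2, 2, cout) + b
    return t.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * wd, cout)


def _upconv_bwd(dy: np.ndarray, x: np.ndarray, w: np.ndarray):
    n, h, wd, c = x.shape
    cout = w.shape[1] // 4
    dt = (dy.reshape(n, h, 2, wd, 2, cout)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(-1, 4 * cout))
    dw = x.reshape(-1, c).T @ dt
    db = dy.reshape(-1, cout).sum(axis=0)
    dx = (dt @ w.T).reshape(n, h, wd, c)
    return dx, dw, db


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# The model


class UNet:
    """U-Net with same-padding convolutions and skip concatenation.

    Weights live in ``self.params`` (a flat name -> float32 array dict) so the
    optimizer and checkpointing stay trivial. Use :func:`train` to fit and
    :func:`predict` to segment a full composite image.
    """

    def __init__(self, config: NetConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- construction ------------------------------------------------------

    def _add_conv(self, rng, name: str, cin: int, cout: int) -> None:
        std = np.sqrt(2.0 / (9 * cin))  # He init for ReLU
        self.params[f"{name}_W"] = rng.normal(0.0, std, (9 * cin, cout)).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

    def _init_params(self, rng) -> None:
        cfg = self.config
        cin = cfg.in_channels
        for i in range(cfg.depth):
            f = cfg.base_filters * 2 ** i
            self._add_conv(rng, f"enc{i}_conv1", cin, f)
            self._add_conv(rng, f"enc{i}_conv2", f, f)
            cin = f
        fb = cfg.base_filters * 2 ** cfg.depth
        self._add_conv(rng, "bott_conv1", cin, fb)
        self._add_conv(rng, "bott_conv2", fb, fb)
        cin = fb
        for i in reversed(range(cfg.depth)):
            f = cfg.base_filters * 2 ** i
            std = np.sqrt(2.0 / cin)
            self.params[f"dec{i}_up_W"] = rng.normal(0.0, std, (cin, 4 * f)).astype(np.float32)
            self.params[f"dec{i}_up_b"] = np.zeros(f, dtype=np.float32)
            self._add_conv(rng, f"dec{i}_conv1", 2 * f, f)
            self._add_conv(rng, f"dec{i}_conv2", f, f)
            cin = f
        std = np.sqrt(1.0 / cin)
        self.params["out_W"] = rng.normal(0.0, std, (cin, 1)).astype(np.float32)
        self.params["out_b"] = np.zeros(1, dtype=np.float32)

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        n, h, w, c = x.shape
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {div}; pad or retile first"
            )
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input channels, got {c}")

    def _conv_block(self, x, name, cache):
        p = self.params
        z1, xp1 = _conv3x3_fwd(x, p[f"{name}_conv1_W"], p[f"{name}_conv1_b"])
        np.maximum(z1, 0.0, out=z1)
        z2, xp2 = _conv3x3_fwd(z1, p[f"{name}_conv2_W"], p[f"{name}_conv2_b"])
        np.maximum(z2, 0.0, out=z2)
        if cache is not None:
            # conv1's ReLU mask comes free from xp2's interior (= relu(z1));
            # only conv2's mask needs explicit storage
            cache[name] = (xp1, xp2, z2 > 0)
        return z2

    def _conv_block_bwd(self, da2, name, cache, grads):
        p = self.params
        xp1, xp2, m2 = cache.pop(name)
        dz2 = da2 * m2
        da1, dw2, db2 = _conv3x3_bwd(dz2, xp2, p[f"{name}_conv2_W"])
        grads[f"{name}_conv2_W"] = dw2
        grads[f"{name}_conv2_b"] = db2
        dz1 = da1
        dz1 *= xp2[:, 1:-1, 1:-1, :] > 0
        dx, dw1, db1 = _conv3x3_bwd(dz1, xp1, p[f"{name}_conv1_W"])
        grads[f"{name}_conv1_W"] = dw1
        grads[f"{name}_conv1_b"] = db1
        return dx

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Probabilities (N, H, W) for a batch (N, H, W, C) in [0, 1]."""
        # float64 input keeps a full double-precision path (used by the
        # gradient tests); everything else runs in float32 for speed
        dtype = np.float64 if np.asarray(x).dtype == np.float64 else np.float32
        x = np.ascontiguousarray(x, dtype=dtype)
        self._check_input(x)
        cfg = self.config
        skips = []
        h = x
        for i in range(cfg.depth):
            a = self._conv_block(h, f"enc{i}", cache)
            skips.append(a)
            h, pool_cache = _maxpool_fwd(a)
            if cache is not None:
                cache[f"pool{i}"] = pool_cache
        h = self._conv_block(h, "bott", cache)
        for i in reversed(range(cfg.depth)):
            up = _upconv_fwd(h, self.params[f"dec{i}_up_W"], self.params[f"dec{i}_up_b"])
            if cache is not None:
                cache[f"up{i}_in"] = h
            skip = skips[i]
            h = np.concatenate([skip, up], axis=-1)
            h = self._conv_block(h, f"dec{i}", cache)
        z = h.reshape(-1, h.shape[-1]) @ self.params["out_W"] + self.params["out_b"]
        z = z.reshape(h.shape[0], h.shape[1], h.shape[2])
        if cache is not None:
            cache["out_in"] = h
        prob = _sigmoid(z)
        if cache is not None:
            cache["prob"] = prob
        return prob

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """BCE loss and parameter gradients for one batch.

        ``y`` is (N, H, W) binary. The sigmoid and the clamped cross-entropy
        combine into the numerically stable gradient (prob - y) / N at the
        logit, so no log of a small number is ever differentiated.
        """
        cache: dict = {}
        prob = self.forward(x, cache)
        loss = bce_loss(y, prob)
        if not np.isfinite(loss):
            raise FloatingPointError("training diverged: loss is not finite")
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        n_pix = prob.size
        dz = ((prob - y.astype(prob.dtype)) / n_pix).astype(prob.dtype)
        hout = cache.pop("out_in")
        dz2 = dz.reshape(-1, 1)
        grads["out_W"] = hout.reshape(-1, hout.shape[-1]).T @ dz2
        grads["out_b"] = dz2.sum(axis=0)
        dh = (dz2 @ self.params["out_W"].T).reshape(hout.shape)
        for i in range(cfg.depth):
            dh = self._conv_block_bwd(dh, f"dec{i}", cache, grads)
            f = cfg.base_filters * 2 ** i
            dskip, dup = dh[..., :f], dh[..., f:]
            up_in = cache.pop(f"up{i}_in")
            dh, dwu, dbu = _upconv_bwd(dup, up_in, self.params[f"dec{i}_up_W"])
            grads[f"dec{i}_up_W"] = dwu
            grads[f"dec{i}_up_b"] = dbu
            # gradient flowing through the skip joins after the encoder block
            cache[f"skipgrad{i}"] = dskip
        dh = self._conv_block_bwd(dh, "bott", cache, grads)
        for i in reversed(range(cfg.depth)):
            da = _maxpool_bwd(dh, cache.pop(f"pool{i}")) + cache.pop(f"skipgrad{i}")
            dh = self._conv_block_bwd(da, f"enc{i}", cache, grads)
        return loss, grads

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Serialize weights plus configuration to a single ``.npz`` checkpoint."""
        arrays = dict(self.params)
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as data:
            cfg = NetConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls.__new__(cls)
            model.config = cfg
            model.params = {k: data[k] for k in data.files if k != "__config__"}
        return model


# ---------------------------------------------------------------------------
# Optimizer


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Training and inference


def _stack_examples(examples: Sequence[TrainingExample]):
    x = np.stack([e.patch.transpose(1, 2, 0) for e in examples]).astype(np.float32)
    y = np.stack([e.target for e in examples]).astype(np.float32)
    return x, y


def _augment_batch(xb: np.ndarray, yb: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    if rng.random() < 0.5:
        xb, yb = xb[:, ::-1], yb[:, ::-1]
    if rng.random() < 0.5:
        xb, yb = xb[:, :, ::-1], yb[:, :, ::-1]
    k = int(rng.integers(4))
    if k:
        xb = np.rot90(xb, k, axes=(1, 2))
        yb = np.rot90(yb, k, axes=(1, 2))
    return np.ascontiguousarray(xb), np.ascontiguousarray(yb)


def _eval_loss(model: UNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total = 0.0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        total += bce_loss(yb, model.forward(xb)) * len(xb)
    return total / len(x)


def train(model: UNet, examples: Sequence[TrainingExample],
          config: NetConfig | None = None) -> list[dict]:
    """Fit the model in place; return the per-epoch training log.

    A seeded fraction of the examples is held out for validation. Each epoch
    shuffles the training set, runs Adam over batches, then measures the
    validation loss; training stops at ``max_epochs`` or once the validation
    loss has not improved for ``early_stop_patience`` epochs, and the weights
    of the best epoch are restored. The log holds one record per epoch:
    ``{"epoch", "train_loss", "val_loss"}``.
    """
    cfg = config if config is not None else model.config
    if len(examples) < 2:
        raise ValueError("need at least 2 examples for a train/validation split")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(examples))
    n_val = max(1, int(round(cfg.validation_fraction * len(examples))))
    if n_val >= len(examples):
        n_val = len(examples) - 1
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_all, y_all = _stack_examples(examples)
    x_tr, y_tr = x_all[train_idx], y_all[train_idx]
    x_va, y_va = x_all[val_idx], y_all[val_idx]

    opt = _Adam(model.params, lr=cfg.learning_rate)
    log: list[dict] = []
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        total, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            if cfg.augment:
                xb, yb = _augment_batch(xb, yb, rng)
            loss, grads = model.loss_and_grads(xb, yb)
            opt.step(model.params, grads)
            total += loss * len(sel)
            seen += len(sel)
        val_loss = _eval_loss(model, x_va, y_va, cfg.batch_size)
        log.append({"epoch": epoch, "train_loss": total / seen, "val_loss": val_loss})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    if best_params is not None:
        model.params = best_params
    return log


def predict(model: UNet, composite: CompositeImage) -> np.ndarray:
    """Segment a full composite: tile, forward each tile, reassemble.

    Returns a float probability map with the composite's exact height and
    width, every value in [0, 1].
    """
    size = model.config.patch_size
    patches = split_patches(composite, size)
    x = np.stack([p.pixels.transpose(1, 2, 0) for p in patches]).astype(np.float32)
    probs = []
    for i in range(0, len(x), model.config.batch_size):
        probs.append(model.forward(x[i:i + model.config.batch_size]))
    tiles = list(np.concatenate(probs, axis=0))
    return merge_patches(tiles, patches, composite.height, composite.width)
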