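"""Patch autoencoders whose bottleneck codes feed the feature statistics.

Two autoencoders are used: one on 128-px low-magnification patches (code
width 2048 by default) and one on 28-px high-magnification sub-patches
(code width 1568 by default).  Downstream statistics depend only on the
code width, so the architecture is deliberately small and configurable: a
stack of non-overlapping block convolutions (kernel size = stride, i.e. a
shared linear map per image block) with leaky ReLU, a fully connected
softplus bottleneck of exactly ``code_dim`` units, and a mirrored decoder
ending in a sigmoid over RGB.  The bottleneck activation is strictly
positive so that per-unit argmax scoring is meaningful, and has no dead
zone, which matters for the short training runs used here.

Everything is plain numpy with manual backpropagation and Adam, which keeps
training single-threaded, deterministic under a fixed seed, and fast enough
for desk-scale synthetic experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class EncoderConfig:
    """Architecture and training hyperparameters of one patch autoencoder.

    ``conv_blocks`` is a sequence of ``(block_size, channels)`` stages; each
    stage partitions its input into non-overlapping ``block_size`` squares
    and applies a shared linear map to ``channels`` output channels followed
    by ReLU.  The product of block sizes must divide ``input_size_px``.
    """

    input_size_px: int
    code_dim: int
    conv_blocks: tuple[tuple[int, int], ...] = ((8, 32),)
    channels_in: int = 3
    epochs: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.code_dim < 1:
            raise ValueError("code_dim must be >= 1")
        size = self.input_size_px
        for b, c in self.conv_blocks:
            if size % b:
                raise ValueError(
                    f"block size {b} does not divide remaining extent {size}"
                )
            size //= b
        self._spatial = size  # spatial extent after all conv stages

    @property
    def conv_output_dim(self) -> int:
        c = self.conv_blocks[-1][1] if self.conv_blocks else self.channels_in
        return self._spatial * self._spatial * c


def low_magnification_config(**overrides) -> EncoderConfig:
    """Default 128-px configuration with a 2048-unit bottleneck."""
    kw = dict(input_size_px=128, code_dim=2048, conv_blocks=((8, 32),))
    kw.update(overrides)
    return EncoderConfig(**kw)


def high_magnification_config(**overrides) -> EncoderConfig:
    """Default 28-px configuration with a 1568-unit bottleneck."""
    kw = dict(input_size_px=28, code_dim=1568, conv_blocks=((7, 24),))
    kw.update(overrides)
    return EncoderConfig(**kw)


# ---------------------------------------------------------------------------
# layers (numpy, manual backprop)
# ---------------------------------------------------------------------------


def _patchify(x: np.ndarray, b: int) -> np.ndarray:
    n, h, w, c = x.shape
    return (x.reshape(n, h // b, b, w // b, b, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h // b, w // b, b * b * c))


def _unpatchify(p: np.ndarray, b: int, c: int) -> np.ndarray:
    n, h, w, _ = p.shape
    return (p.reshape(n, h, w, b, b, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h * b, w * b, c))


class _Op:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _LeakyRelu(_Op):
    """Leaky ReLU: keeps a small gradient on the negative side so hidden
    units cannot die irrecoverably during the short training runs."""

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._mask, g, self.alpha * g)


class _Softplus(_Op):
    """Softplus bottleneck: strictly positive activations (so per-unit
    argmax scoring is meaningful) with a nowhere-zero gradient."""

    def forward(self, x):
        self._sig = 1.0 / (1.0 + np.exp(-x))
        return np.where(x > 20, x, np.log1p(np.exp(np.minimum(x, 20.0))))

    def backward(self, g):
        return g * self._sig


class _Sigmoid(_Op):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class _Linear(_Op):
    """Shared linear map over the last axis (used spatially and densely)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.grads[0][...] = x2.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        return g @ self.W.T


class _BlockDown(_Op):
    """Patchify by ``b`` then shared linear map (convolution, kernel=stride)."""

    def __init__(self, b: int, c_in: int, c_out: int, rng):
        self.b, self.c_in = b, c_in
        self.lin = _Linear(b * b * c_in, c_out, rng)
        self.params, self.grads = self.lin.params, self.lin.grads

    def forward(self, x):
        return self.lin.forward(_patchify(x, self.b))

    def backward(self, g):
        gp = self.lin.backward(g)
        return _unpatchify(gp, self.b, self.c_in)


class _BlockUp(_Op):
    """Shared linear map to ``b*b*c_out`` channels then un-patchify."""

    def __init__(self, b: int, c_in: int, c_out: int, rng):
        self.b, self.c_out = b, c_out
        self.lin = _Linear(c_in, b * b * c_out, rng)
        self.params, self.grads = self.lin.params, self.lin.grads

    def forward(self, x):
        return _unpatchify(self.lin.forward(x), self.b, self.c_out)

    def backward(self, g):
        return self.lin.backward(_patchify(g, self.b))


class _Reshape(_Op):
    def __init__(self, shape_in: tuple, shape_out: tuple):
        self.shape_in, self.shape_out = shape_in, shape_out

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape_out)

    def backward(self, g):
        return g.reshape((g.shape[0],) + self.shape_in)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the autoencoder
# ---------------------------------------------------------------------------


class Autoencoder:
    """Convolutional patch autoencoder with a fully connected bottleneck."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        self.fitted = False
        self.loss_history: list[float] = []
        self._build()

    def _build(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xAE]))
        h = cfg.input_size_px
        c = cfg.channels_in
        enc: list[_Op] = []
        for b, c_out in cfg.conv_blocks:
            enc += [_BlockDown(b, c, c_out, rng), _LeakyRelu()]
            h //= b
            c = c_out
        conv_shape = (h, h, c)
        d = h * h * c
        enc += [_Reshape(conv_shape, (d,)),
                _Linear(d, cfg.code_dim, rng), _Softplus()]
        dec: list[_Op] = [_Linear(cfg.code_dim, d, rng), _LeakyRelu(),
                          _Reshape((d,), conv_shape)]
        rev = list(cfg.conv_blocks)[::-1]
        for i, (b, c_out) in enumerate(rev):
            c_next = rev[i + 1][1] if i + 1 < len(rev) else cfg.channels_in
            dec += [_BlockUp(b, c_out, c_next, rng)]
            dec += [_Sigmoid() if i + 1 == len(rev) else _LeakyRelu()]
        self._encoder, self._decoder = enc, dec
        self._ops = enc + dec

    # -- training ----------------------------------------------------------

    @staticmethod
    def _as_float(patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        return x.astype(np.float32, copy=False)

    def _check_shape(self, x: np.ndarray) -> None:
        cfg = self.config
        expect = (cfg.input_size_px, cfg.input_size_px, cfg.channels_in)
        if x.ndim != 4 or x.shape[1:] != expect:
            raise ValueError(
                f"patch array of shape {x.shape} does not match the "
                f"configured input {expect}"
            )

    def _forward(self, x: np.ndarray, ops: Sequence[_Op]) -> np.ndarray:
        for op in ops:
            x = op.forward(x)
        return x

    def reconstruction_loss(self, patches: np.ndarray,
                            batch_size: int = 256) -> float:
        """Mean squared reconstruction error over ``patches`` (no training)."""
        x = self._as_float(patches)
        self._check_shape(x)
        total, n = 0.0, 0
        for s in range(0, len(x), batch_size):
            xb = x[s:s + batch_size]
            y = self._forward(xb, self._ops)
            total += float(((y - xb) ** 2).sum())
            n += xb.size
        return total / n

    def fit(self, patches: np.ndarray) -> "Autoencoder":
        """Train to minimise mean squared reconstruction error.

        Deterministic under the configured seed: initialisation, batch order
        and optimiser state are all driven by it.
        """
        x = self._as_float(patches)
        self._check_shape(x)
        if len(x) < 2:
            raise ValueError("need at least 2 patches to train")
        cfg = self.config
        self.initial_loss = self.reconstruction_loss(x)
        params = [p for op in self._ops for p in op.params]
        grads = [g for op in self._ops for g in op.grads]
        opt = _Adam(params, cfg.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBA7C4]))
        self.loss_history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(x))
            epoch_loss, seen = 0.0, 0
            for s in range(0, len(x), cfg.batch_size):
                xb = x[order[s:s + cfg.batch_size]]
                y = self._forward(xb, self._ops)
                loss = float(((y - xb) ** 2).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "non-finite reconstruction loss during training; "
                        "try a lower learning rate"
                    )
                g = (2.0 / y.size) * (y - xb)
                for op in reversed(self._ops):
                    g = op.backward(g)
                opt.step(grads)
                epoch_loss += loss * xb.size
                seen += xb.size
            if not all(np.isfinite(p).all() for p in params):
                raise FloatingPointError(
                    "non-finite weights during training; "
                    "try a lower learning rate"
                )
            self.loss_history.append(epoch_loss / seen)
        self.final_loss = self.reconstruction_loss(x)
        self.fitted = True
        return self

    # -- inference ---------------------------------------------------------

    def encode(self, patches: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Bottleneck codes, one row per patch (pure function of the weights).

        Codes are the post-softplus bottleneck activations, hence positive.
        """
        if not self.fitted:
            raise RuntimeError("autoencoder is untrained; call fit() first")
        x = self._as_float(patches)
        self._check_shape(x)
        out = np.empty((len(x), self.config.code_dim), dtype=np.float32)
        for s in range(0, len(x), batch_size):
            out[s:s + batch_size] = self._forward(x[s:s + batch_size],
                                                  self._encoder)
        return out

    def reconstruct(self, patches: np.ndarray) -> np.ndarray:
        x = self._as_float(patches)
        self._check_shape(x)
        return self._forward(x, self._ops)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: JSON config header plus weight arrays."""
        header = json.dumps({
            "config": {k: v for k, v in asdict(self.config).items()},
            "fitted": self.fitted,
            "loss_history": self.loss_history,
        })
        arrays = {f"p{i}": p
                  for i, p in enumerate(p for op in self._ops for p in op.params)}
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Autoencoder":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            cfg_dict = dict(header["config"])
            cfg_dict["conv_blocks"] = tuple(
                tuple(b) for b in cfg_dict["conv_blocks"])
            ae = cls(EncoderConfig(**cfg_dict))
            params = [p for op in ae._ops for p in op.params]
            for i, p in enumerate(params):
                p[...] = data[f"p{i}"]
        ae.fitted = header["fitted"]
        ae.loss_history = list(header["loss_history"])
        return ae


def train_autoencoder(patches: np.ndarray, config: EncoderConfig) -> Autoencoder:
    """Train a fresh autoencoder on ``patches`` under ``config``."""
    return Autoencoder(config).fit(patches)


def encode(encoder: Autoencoder, patches: np.ndarray) -> np.ndarray:
    """Bottleneck code matrix for ``patches`` (rows align with input order)."""
    return encoder.encode(patches)
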