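"""Dual-branch 3D/2D convolutional classifier.

A 3D-convolution branch extracts joint spatial-spectral features from the 33
albedo channels of each 30x30x34 window; a 2D-convolution branch processes the
single skin-surface channel.  Branch outputs are flattened, concatenated and
passed through dense hidden layers to a softmax output (3 or 4 classes).
LeakyReLU activations, max pooling, Adam at default hyperparameters,
categorical cross-entropy, early stopping on validation loss.

Implemented directly on NumPy: convolutions accumulate shifted views of the
input against each kernel offset, which is exact and fast for the small
kernels used here, and keeps training fully deterministic under a fixed seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hsiderm.mlprep import N_FEATURE_CHANNELS
from hsiderm.photometric import N_BANDS

PATCH_SIDE = 30


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #


@dataclass
class ModelConfig:
    n_classes: int = 3
    conv3d_spec: list = field(default_factory=lambda: [(8, (3, 3, 7)), (16, (3, 3, 5))])
    pool3d_spec: list = field(default_factory=lambda: [(2, 2, 2), (2, 2, 2)])
    conv2d_spec: list = field(default_factory=lambda: [(8, (3, 3)), (16, (3, 3))])
    pool2d_spec: list = field(default_factory=lambda: [(2, 2), (2, 2)])
    dense_units: list = field(default_factory=lambda: [128, 64])
    leaky_slope: float = 0.1
    learning_rate: float = 1e-3  # Adam defaults: beta1 0.9, beta2 0.999
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (3, 4):
            raise ValueError("n_classes must be 3 or 4")
        if len(self.conv3d_spec) != len(self.pool3d_spec):
            raise ValueError("conv3d_spec and pool3d_spec lengths differ")
        if len(self.conv2d_spec) != len(self.pool2d_spec):
            raise ValueError("conv2d_spec and pool2d_spec lengths differ")


def small_config(n_classes: int = 3, **overrides) -> ModelConfig:
    """Reduced architecture for CPU-bound runs; same structural layout."""
    cfg = dict(
        n_classes=n_classes,
        conv3d_spec=[(4, (3, 3, 7))],
        pool3d_spec=[(2, 2, 3)],
        conv2d_spec=[(4, (3, 3))],
        pool2d_spec=[(2, 2)],
        dense_units=[32],
        learning_rate=3e-3,
        batch_size=16,
        max_epochs=5,
        patience=3,
    )
    cfg.update(overrides)
    return ModelConfig(**cfg)


# --------------------------------------------------------------------------- #
# layers
# --------------------------------------------------------------------------- #


class _ConvND:
    """Valid-mode convolution over the leading spatial dims (2 or 3 of them).

    Two equivalent compute paths: a windowed-view tensordot (fastest when the
    input has a single channel, i.e. the first layer of a branch, where the
    per-offset temporaries of the alternative dominate) and a sum of shifted
    input views against each kernel offset.  The first layer of a branch skips
    the input gradient entirely.
    """

    _CHUNK = 8  # batch chunk bounding the windowed-view matmul workspace

    def __init__(self, kernel, c_in, c_out, rng, ndim, first_layer=False):
        self.kernel = tuple(kernel)
        self.ndim = ndim
        self.first_layer = first_layer
        self.use_windowed = c_in == 1
        fan_in = int(np.prod(kernel)) * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=self.kernel + (c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_shape(self, in_shape):
        spatial = tuple(s - k + 1 for s, k in zip(in_shape[: self.ndim], self.kernel))
        if any(s < 1 for s in spatial):
            raise ValueError(
                f"kernel {self.kernel} does not fit input of shape {in_shape[:self.ndim]}"
            )
        return spatial + (self.W.shape[-1],)

    def _offsets(self):
        return np.ndindex(*self.kernel)

    def _windows(self, x):
        """(B, s..., C, k...) strided view of all kernel-sized windows."""
        from numpy.lib.stride_tricks import sliding_window_view

        return sliding_window_view(x, self.kernel, axis=tuple(range(1, self.ndim + 1)))

    def forward(self, x):
        self.x = x
        nd = self.ndim
        spatial = self.out_shape(x.shape[1:])[:-1]
        out = np.empty((x.shape[0],) + spatial + (self.W.shape[-1],),
                       dtype=np.result_type(x.dtype, self.W.dtype))
        if self.use_windowed:
            v_axes = [nd + 1] + list(range(nd + 2, 2 * nd + 2))
            w_axes = [nd] + list(range(nd))
            for i in range(0, x.shape[0], self._CHUNK):
                v = self._windows(x[i : i + self._CHUNK])
                out[i : i + self._CHUNK] = np.tensordot(v, self.W, axes=(v_axes, w_axes))
            out += self.b
        else:
            out[:] = self.b
            for off in self._offsets():
                view = x[(slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))]
                out += np.tensordot(view, self.W[off], axes=([nd + 1], [0]))
        return out

    def backward(self, dout):
        nd = self.ndim
        spatial = dout.shape[1:-1]
        batch_spatial = tuple(range(nd + 1))
        if self.use_windowed:
            dw = np.zeros(self.W.shape[-2:] + self.kernel, dtype=self.dW.dtype)
            for i in range(0, self.x.shape[0], self._CHUNK):
                v = self._windows(self.x[i : i + self._CHUNK])
                # (B, s..., C, k...) x (B, s..., O) -> (C, k..., O)
                dw += np.moveaxis(
                    np.tensordot(v, dout[i : i + self._CHUNK],
                                 axes=(batch_spatial, batch_spatial)), -1, 1)
            self.dW[:] = np.moveaxis(dw, (0, 1), (nd, nd + 1))
        else:
            for off in self._offsets():
                sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
                self.dW[off] = np.tensordot(self.x[sl], dout,
                                            axes=(batch_spatial, batch_spatial))
        self.db[:] = dout.sum(axis=batch_spatial)
        dx = None
        if not self.first_layer:
            dx = np.zeros_like(self.x)
            for off in self._offsets():
                sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
                dx[sl] += np.tensordot(dout, self.W[off], axes=([nd + 1], [1]))
        self.x = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _LeakyReLU:
    def __init__(self, slope):
        self.slope = np.float32(slope)

    def forward(self, x):
        self.mask = x > 0
        return np.where(self.mask, x, self.slope * x)

    def backward(self, dout):
        out = np.where(self.mask, dout, self.slope * dout)
        self.mask = None
        return out


class _MaxPoolND:
    """Non-overlapping max pooling; trailing remainders are truncated."""

    def __init__(self, pool, ndim):
        self.pool = tuple(pool)
        self.ndim = ndim

    def out_shape(self, in_shape):
        spatial = tuple(s // p for s, p in zip(in_shape[: self.ndim], self.pool))
        if any(s < 1 for s in spatial):
            raise ValueError(f"pool {self.pool} does not fit input shape {in_shape}")
        return spatial + (in_shape[-1],)

    def forward(self, x):
        self.in_shape = x.shape
        b, c = x.shape[0], x.shape[-1]
        spatial = tuple(s // p for s, p in zip(x.shape[1 : 1 + self.ndim], self.pool))
        trunc = x[(slice(None),) + tuple(slice(0, s * p) for s, p in zip(spatial, self.pool))]
        # interleave (out_dim, pool_dim) pairs, then collapse the pool dims
        shape = (b,)
        for s, p in zip(spatial, self.pool):
            shape += (s, p)
        shape += (c,)
        r = trunc.reshape(shape)
        perm = (0,) + tuple(1 + 2 * i for i in range(self.ndim)) + (1 + 2 * self.ndim,) \
            + tuple(2 + 2 * i for i in range(self.ndim))
        r = r.transpose(perm).reshape((b,) + spatial + (c, -1))
        self.argmax = r.argmax(axis=-1)
        return np.take_along_axis(r, self.argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        b, c = dout.shape[0], dout.shape[-1]
        spatial = dout.shape[1:-1]
        flat = np.zeros((b,) + spatial + (c, int(np.prod(self.pool))), dtype=dout.dtype)
        np.put_along_axis(flat, self.argmax[..., None], dout[..., None], axis=-1)
        # axes (b, s..., c, p...) -> invert the forward transpose back to the
        # interleaved (b, s1, p1, s2, p2, ..., c) layout, then merge the pairs
        grad = flat.reshape((b,) + spatial + (c,) + self.pool)
        perm = (0,) + tuple(1 + 2 * i for i in range(self.ndim)) + (1 + 2 * self.ndim,) \
            + tuple(2 + 2 * i for i in range(self.ndim))
        grad = grad.transpose(np.argsort(np.array(perm)))
        merged = grad.reshape((b,) + tuple(s * p for s, p in zip(spatial, self.pool)) + (c,))
        dx = np.zeros(self.in_shape, dtype=dout.dtype)
        dx[(slice(None),) + tuple(slice(0, s * p) for s, p in zip(spatial, self.pool))] = merged
        self.argmax = None
        return dx


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[:] = self.x.T @ dout
        self.db[:] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self.x = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------- #
# network
# --------------------------------------------------------------------------- #


class DualBranchCNN:
    """Input (B, 30, 30, 34): channels 0-32 feed the volumetric branch,
    channel 33 the planar branch."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.branch3d, shape3d = self._build_branch(
            config.conv3d_spec, config.pool3d_spec, (PATCH_SIDE, PATCH_SIDE, N_BANDS, 1),
            rng, ndim=3, slope=config.leaky_slope)
        self.branch2d, shape2d = self._build_branch(
            config.conv2d_spec, config.pool2d_spec, (PATCH_SIDE, PATCH_SIDE, 1),
            rng, ndim=2, slope=config.leaky_slope)
        self.n3d = int(np.prod(shape3d))
        self.n2d = int(np.prod(shape2d))
        self.head = []
        n_in = self.n3d + self.n2d
        for units in config.dense_units:
            self.head.append(_Dense(n_in, units, rng))
            self.head.append(_LeakyReLU(config.leaky_slope))
            n_in = units
        self.head.append(_Dense(n_in, config.n_classes, rng))

    @staticmethod
    def _build_branch(conv_spec, pool_spec, in_shape, rng, ndim, slope):
        layers = []
        shape = in_shape
        for li, ((filters, kernel), pool) in enumerate(zip(conv_spec, pool_spec)):
            conv = _ConvND(kernel, shape[-1], filters, rng, ndim=ndim, first_layer=li == 0)
            shape = conv.out_shape(shape)
            layers.append(conv)
            layers.append(_LeakyReLU(slope))
            pool_layer = _MaxPoolND(pool, ndim=ndim)
            shape = pool_layer.out_shape(shape)
            layers.append(pool_layer)
        return layers, shape

    # ---- forward / backward ------------------------------------------------

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != (PATCH_SIDE, PATCH_SIDE, N_FEATURE_CHANNELS):
            raise ValueError(
                f"expected patches of shape (B, {PATCH_SIDE}, {PATCH_SIDE}, "
                f"{N_FEATURE_CHANNELS}), got {x.shape}"
            )
        a = x[..., :N_BANDS, None]
        b = x[..., N_BANDS:]
        for layer in self.branch3d:
            a = layer.forward(a)
        for layer in self.branch2d:
            b = layer.forward(b)
        self._shape3d, self._shape2d = a.shape, b.shape
        z = np.concatenate([a.reshape(len(a), -1), b.reshape(len(b), -1)], axis=1)
        for layer in self.head:
            z = layer.forward(z)
        return _softmax(z)

    def backward(self, dlogits):
        dz = dlogits
        for layer in reversed(self.head):
            dz = layer.backward(dz)
        da = dz[:, : self.n3d].reshape(self._shape3d)
        db = dz[:, self.n3d :].reshape(self._shape2d)
        for layer in reversed(self.branch3d):
            da = layer.backward(da)
        for layer in reversed(self.branch2d):
            db = layer.backward(db)

    def param_layers(self):
        out = []
        for layer in self.branch3d + self.branch2d + self.head:
            if hasattr(layer, "params"):
                out.extend(layer.params())
        return out

    def get_weights(self):
        return [(getattr(l, name).copy()) for name, l in self.param_layers()]

    def set_weights(self, weights):
        for (name, l), w in zip(self.param_layers(), weights):
            getattr(l, name)[:] = w


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, n)) for n, l in params]
        self.v = [np.zeros_like(getattr(l, n)) for n, l in params]
        self.t = 0

    def step(self):
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for i, (name, layer) in enumerate(self.params):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = self.lr * (self.m[i] / corr1) / (np.sqrt(self.v[i] / corr2) + self.eps)
            getattr(layer, name)[...] -= update


# --------------------------------------------------------------------------- #
# training and prediction
# --------------------------------------------------------------------------- #


@dataclass
class TrainedModel:
    network: DualBranchCNN
    class_order: list
    config: ModelConfig
    training_log: list


def build_model(config: ModelConfig) -> DualBranchCNN:
    return DualBranchCNN(config)


def samples_to_arrays(samples, class_order):
    """(patches, label indices) from WindowSamples; unknown labels raise."""
    index = {c: i for i, c in enumerate(class_order)}
    ys = []
    for s in samples:
        if s.label not in index:
            raise ValueError(f"label {s.label!r} outside class order {class_order}")
        ys.append(index[s.label])
    x = np.stack([s.patch for s in samples]).astype(np.float32)
    return x, np.asarray(ys, dtype=np.int64)


def _evaluate(net, x, y, batch_size):
    loss, correct = 0.0, 0
    for i in range(0, len(x), batch_size):
        probs = net.forward(x[i : i + batch_size])
        yy = y[i : i + batch_size]
        loss += -np.log(np.maximum(probs[np.arange(len(yy)), yy], 1e-12)).sum()
        correct += int((probs.argmax(axis=1) == yy).sum())
    return loss / len(x), correct / len(x)


def train(
    model: DualBranchCNN,
    train_samples,
    val_samples,
    config: ModelConfig,
    class_order=None,
) -> TrainedModel:
    """Adam + categorical cross-entropy with early stopping on validation
    loss (``config.patience``); fully deterministic given ``config.seed``."""
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    if class_order is None:
        class_order = sorted({s.label for s in train_samples} | {s.label for s in val_samples})
    if len(class_order) != config.n_classes:
        raise ValueError(
            f"{len(class_order)} classes present but model has {config.n_classes} outputs"
        )
    x_tr, y_tr = samples_to_arrays(train_samples, class_order)
    x_va, y_va = samples_to_arrays(val_samples, class_order)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    optimizer = _Adam(model.param_layers(), config.learning_rate)
    log = []
    best_loss, best_weights, since_best = np.inf, model.get_weights(), 0
    n = len(x_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs = model.forward(xb)
            ep_loss += -np.log(np.maximum(probs[np.arange(len(yb)), yb], 1e-12)).sum()
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            model.backward(grad / len(yb))
            optimizer.step()
        val_loss, val_acc = _evaluate(model, x_va, y_va, config.batch_size)
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(ep_loss / n),
                "train_accuracy": ep_correct / n,
                "val_loss": float(val_loss),
                "val_accuracy": float(val_acc),
            }
        )
        if val_loss < best_loss - 1e-9:
            best_loss, best_weights, since_best = val_loss, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_weights(best_weights)
    return TrainedModel(network=model, class_order=list(class_order),
                        config=config, training_log=log)


def predict(model: TrainedModel, patches, batch_size: int = 256) -> np.ndarray:
    """Probability matrix; rows follow input order, columns ``class_order``."""
    if isinstance(patches, (list, tuple)) and patches and hasattr(patches[0], "patch"):
        patches = np.stack([s.patch for s in patches])
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    out = np.empty((len(x), model.config.n_classes), dtype=np.float64)
    for i in range(0, len(x), batch_size):
        out[i : i + batch_size] = model.network.forward(x[i : i + batch_size])
    return out


# --------------------------------------------------------------------------- #
# checkpointing
# --------------------------------------------------------------------------- #


def save_model(model: TrainedModel, path) -> None:
    """Weights in an .npz container plus a JSON architecture manifest."""
    path = Path(path)
    weights = model.network.get_weights()
    np.savez(path, **{f"w{i}": w for i, w in enumerate(weights)})
    manifest = {
        "class_order": model.class_order,
        "training_log": model.training_log,
        "config": {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in vars(model.config).items()
        },
    }
    path.with_suffix(".json").write_text(json.dumps(manifest))


def load_model(path) -> TrainedModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    raw = manifest["config"]
    cfg = ModelConfig(
        **{
            k: ([tuple(t) if isinstance(t, list) else t for t in v] if isinstance(v, list) else v)
            for k, v in raw.items()
        }
    )
    net = DualBranchCNN(cfg)
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    return TrainedModel(network=net, class_order=manifest["class_order"],
                        config=cfg, training_log=manifest["training_log"])
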