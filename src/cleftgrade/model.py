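"""Multi-view CNN severity classifier with attention view aggregation.

Each rendered view (normal + depth channels) passes through a shared small
2D conv encoder; the per-view feature maps of the final convolutional layer
are globally average-pooled into per-view descriptors, which a gated
attention layer (attention-based multiple-instance pooling: softmax over
``w^T (tanh(U h_v) * sigmoid(V h_v))``) combines into one convex mixture.
A linear head yields 4 severity logits.

The network is implemented directly on NumPy arrays with hand-written
forward/backward passes (im2col convolutions, Adam updates).  This keeps the
whole pipeline dependency-light and, importantly, gives SurfGradCAM exact
analytic gradients of any class logit with respect to the final conv maps —
including the path through the attention weights.

All floating point work is float32; training is deterministic for a fixed
seed and thread-pinned BLAS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .mesh_io import TriangleMesh, normalize_pose
from .render import render_all
from .views import ViewSet

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "AttentionWeights",
    "ClassProbabilities",
    "MultiViewCNN",
    "train",
    "predict",
    "encode_view",
    "attention_aggregate",
    "classify",
]

N_CLASSES = 4


# ---------------------------------------------------------------------------
# configs and small result containers


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_channels`` lists the output channels of the stride-2 conv blocks;
    the last entry is K, the number of final conv maps SurfGradCAM weights.
    Three stride-2 blocks keep the final maps at 1/8 of the render resolution
    (8 x 8 at 64 px), fine enough for the surface heatmaps to localize.
    """

    resolution: int = 64
    in_channels: int = 4
    conv_channels: tuple[int, ...] = (16, 32, 64)
    conv_strides: tuple[int, ...] | None = (2, 2, 2)
    attn_dim: int = 32
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.conv_strides is None:
            self.conv_strides = tuple(2 for _ in self.conv_channels)
        if len(self.conv_strides) != len(self.conv_channels):
            raise ValueError("conv_strides must match conv_channels")

    @property
    def feature_dim(self) -> int:
        return self.conv_channels[-1]


@dataclass
class TrainConfig:
    epochs: int = 220
    batch_size: int = 8
    learning_rate: float = 1e-3
    class_weighting: bool = True
    seed: int = 0
    patience: int = 60
    augment: bool = True  # random view flips + shifts each step
    max_shift: int = 6  # translation amplitude, pixels
    cosine_decay: bool = True  # anneal the learning rate to lr/10
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


@dataclass
class AttentionWeights:
    """Convex per-view weights (non-negative, summing to one)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64).ravel()
        if (w < -1e-8).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("attention weights must lie on the simplex")
        self.weights = w


@dataclass
class ClassProbabilities:
    probs: np.ndarray
    logits: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64).ravel()
        l = np.asarray(self.logits, dtype=np.float64).ravel()
        if p.shape != l.shape:
            raise ValueError("probs and logits must have equal length")
        if (p < -1e-8).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must lie on the simplex")
        self.probs, self.logits = p, l

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.probs))


# ---------------------------------------------------------------------------
# conv primitives (im2col)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, c, h, w, ho, wo)


def _col2im(dcols: np.ndarray, shape_info: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, ho, wo = shape_info
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[
                :, :, :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def _conv_forward(x, weight, bias, stride=2, pad=1):
    k = weight.shape[-1]
    cols, info = _im2col(x, k, stride, pad)
    wmat = weight.reshape(weight.shape[0], -1)
    out = cols @ wmat.T
    if bias is not None:
        out += bias
    n, _, _, _, ho, wo = info
    out = out.reshape(n, ho, wo, weight.shape[0]).transpose(0, 3, 1, 2)
    return out, (cols, info, wmat)


def _conv_backward(dout, cache, weight, stride=2, pad=1):
    cols, info, wmat = cache
    n, c, h, w, ho, wo = info
    k = weight.shape[-1]
    dmat = dout.transpose(0, 2, 3, 1).reshape(-1, weight.shape[0])
    dw = (dmat.T @ cols).reshape(weight.shape)
    db = dmat.sum(axis=0)
    dcols = dmat @ wmat
    dx = _col2im(dcols, info, k, stride, pad)
    return dx, dw, db


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# the network


class MultiViewCNN:
    """Shared-encoder multi-view classifier with gated attention pooling."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.params: dict[str, np.ndarray] = {}
        self._init_params(seed)

    # -- parameters -----------------------------------------------------

    def _init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        cfg = self.config
        c_in = cfg.in_channels
        for i, c_out in enumerate(cfg.conv_channels):
            fan_in = c_in * 9
            self.params[f"conv{i}_w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3)
            ).astype(np.float32)
            self.params[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        d, a = cfg.feature_dim, cfg.attn_dim
        self.params["attn_U"] = rng.normal(0, np.sqrt(1.0 / d), (d, a)).astype(np.float32)
        self.params["attn_V"] = rng.normal(0, np.sqrt(1.0 / d), (d, a)).astype(np.float32)
        self.params["attn_w"] = rng.normal(0, np.sqrt(1.0 / a), (a,)).astype(np.float32)
        self.params["head_w"] = rng.normal(
            0, np.sqrt(1.0 / d), (cfg.n_classes, d)
        ).astype(np.float32)
        self.params["head_b"] = np.zeros(cfg.n_classes, dtype=np.float32)

    def save(self, path: str | Path) -> None:
        meta = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "MultiViewCNN":
        data = np.load(path)
        meta = json.loads(bytes(data["__config__"]).decode())
        meta["conv_channels"] = tuple(meta["conv_channels"])
        if meta.get("conv_strides") is not None:
            meta["conv_strides"] = tuple(meta["conv_strides"])
        model = cls(ModelConfig(**meta), seed=0)
        model.params = {k: data[k] for k in data.files if k != "__config__"}
        return model

    # -- encoder --------------------------------------------------------

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        """Conv stack on a batch of views ``(N, C, H, W)`` -> final maps.

        Returns the post-ReLU final conv maps ``(N, K, h, w)`` plus the cache
        needed for backprop.
        """
        cfg = self.config
        if x.shape[1:] != (cfg.in_channels, cfg.resolution, cfg.resolution):
            raise ValueError(
                f"expected input (N, {cfg.in_channels}, {cfg.resolution}, "
                f"{cfg.resolution}), got {x.shape}"
            )
        cache = []
        h = x.astype(np.float32)
        for i in range(len(cfg.conv_channels)):
            z, cv = _conv_forward(h, self.params[f"conv{i}_w"],
                                  self.params[f"conv{i}_b"],
                                  stride=cfg.conv_strides[i])
            mask = z > 0
            h = z * mask
            cache.append((cv, mask))
        return h, cache

    def encoder_backward(self, dmaps: np.ndarray, cache: list) -> dict[str, np.ndarray]:
        grads = {}
        d = dmaps
        for i in reversed(range(len(self.config.conv_channels))):
            cv, mask = cache[i]
            d = d * mask
            d, dw, db = _conv_backward(d, cv, self.params[f"conv{i}_w"],
                                       stride=self.config.conv_strides[i])
            grads[f"conv{i}_w"] = dw
            grads[f"conv{i}_b"] = db
        return grads

    # -- head: GAP + attention + classifier -----------------------------

    def head(self, maps: np.ndarray, n_views: int) -> tuple[np.ndarray, np.ndarray, dict]:
        """From final conv maps ``(B*V, K, h, w)`` to logits ``(B, n_classes)``.

        Returns (logits, attention weights ``(B, V)``, cache).
        """
        p = self.params
        bv, k, hh, ww = maps.shape
        b = bv // n_views
        pooled = maps.mean(axis=(2, 3)).reshape(b, n_views, k)  # h_v
        pre_t = pooled @ p["attn_U"]
        pre_s = pooled @ p["attn_V"]
        t = np.tanh(pre_t)
        s = 1.0 / (1.0 + np.exp(-pre_s))
        gate = t * s
        scores = gate @ p["attn_w"]  # (B, V)
        attn = _softmax(scores, axis=1)
        z = np.einsum("bv,bvd->bd", attn, pooled)
        logits = z @ p["head_w"].T + p["head_b"]
        cache = dict(pooled=pooled, t=t, s=s, gate=gate, attn=attn, z=z,
                     spatial=(hh, ww), n_views=n_views)
        return logits, attn, cache

    def head_backward(
        self, dlogits: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Backprop ``d loss / d logits`` to final-conv-map space.

        Returns (dmaps ``(B*V, K, h, w)``, parameter gradients).
        """
        p = self.params
        pooled, t, s, attn = cache["pooled"], cache["t"], cache["s"], cache["attn"]
        hh, ww = cache["spatial"]
        b, v, d = pooled.shape

        dz = dlogits @ p["head_w"]  # (B, D)
        grads = {
            "head_w": dlogits.T @ cache["z"],
            "head_b": dlogits.sum(axis=0),
        }
        # z = sum_v attn_v h_v
        dattn = np.einsum("bd,bvd->bv", dz, pooled)
        dpooled = attn[:, :, None] * dz[:, None, :]
        # softmax jacobian
        dscores = attn * (dattn - (attn * dattn).sum(axis=1, keepdims=True))
        dgate = dscores[:, :, None] * p["attn_w"]
        dt = dgate * s
        ds = dgate * t
        dpre_t = dt * (1.0 - t * t)
        dpre_s = ds * s * (1.0 - s)
        grads["attn_w"] = np.einsum("bv,bva->a", dscores, cache["gate"])
        grads["attn_U"] = np.einsum("bvd,bva->da", pooled, dpre_t)
        grads["attn_V"] = np.einsum("bvd,bva->da", pooled, dpre_s)
        dpooled += dpre_t @ p["attn_U"].T + dpre_s @ p["attn_V"].T
        dmaps = np.repeat(
            dpooled.reshape(b * v, d)[:, :, None, None] / (hh * ww), hh, axis=2
        ).repeat(ww, axis=3)
        return dmaps.astype(np.float32), grads

    # -- convenience forward passes -------------------------------------

    def forward(self, x: np.ndarray, n_views: int):
        maps, enc_cache = self.encode(x)
        logits, attn, head_cache = self.head(maps, n_views)
        return logits, attn, (maps, enc_cache, head_cache)

    def predict_views(self, views_array: np.ndarray) -> tuple[ClassProbabilities, AttentionWeights]:
        """Classify one shape from its stacked view array ``(V, C, H, W)``."""
        v = views_array.shape[0]
        logits, attn, _ = self.forward(views_array.astype(np.float32), v)
        probs = _softmax(logits, axis=1)
        return (
            ClassProbabilities(probs[0], logits[0]),
            AttentionWeights(attn[0]),
        )

    def grad_logit_wrt_maps(self, maps: np.ndarray, target_class: int,
                            n_views: int) -> np.ndarray:
        """Exact gradient of one class logit w.r.t. the final conv maps.

        Flows through global average pooling, the attention weights and the
        linear head; this is the quantity SurfGradCAM channel weights are
        spatial averages of.
        """
        if not 0 <= target_class < self.config.n_classes:
            raise ValueError(f"target_class must be in 0..{self.config.n_classes - 1}")
        logits, _, cache = self.head(maps, n_views)
        seed = np.zeros_like(logits)
        seed[:, target_class] = 1.0
        dmaps, _ = self.head_backward(seed, cache)
        return dmaps


def _augment_views(x: np.ndarray, rng: np.random.Generator,
                   max_shift: int) -> np.ndarray:
    """Random per-view integer translations (training-time augmentation).

    Where the arch sits in the frame carries no class information, so
    translations are label-preserving; they deny the classifier frame-layout
    shortcuts and push it toward translation-equivariant local detectors,
    which is also what keeps the class-activation maps tied to morphology.
    Image flips are deliberately NOT applied: cleft sidedness is chiral
    information, and the shape generator already mirrors arches at the
    population level.  Vacated pixels take the background value (zero
    normals, depth 1).
    """
    out = np.empty_like(x)
    n = out.shape[0]
    shifts = rng.integers(-max_shift, max_shift + 1, size=(n, 2))
    for i in range(n):
        v = x[i]
        dy, dx = shifts[i]
        if dy or dx:
            h, w = v.shape[1:]
            shifted = np.zeros_like(v)
            shifted[3] = 1.0  # background depth
            ys = slice(max(dy, 0), h + min(dy, 0))
            xs = slice(max(dx, 0), w + min(dx, 0))
            ys_src = slice(max(-dy, 0), h + min(-dy, 0))
            xs_src = slice(max(-dx, 0), w + min(-dx, 0))
            shifted[:, ys, xs] = v[:, ys_src, xs_src]
            out[i] = shifted
        else:
            out[i] = v
    return out


# ---------------------------------------------------------------------------
# rendering-to-tensor plumbing


def views_to_array(rendered, dtype=np.float32) -> np.ndarray:
    """Stack RenderedViews into ``(V, C, H, W)`` with channels first."""
    return np.stack([rv.channels.transpose(2, 0, 1) for rv in rendered]).astype(dtype)


def render_mesh_views(mesh: TriangleMesh, viewset: ViewSet, resolution: int) -> np.ndarray:
    return views_to_array(render_all(normalize_pose(mesh), viewset, resolution))


# ---------------------------------------------------------------------------
# functional wrappers over the model surface


def encode_view(model: MultiViewCNN, view_channels: np.ndarray):
    """Single-view encoding: returns (final conv maps (K, h, w), pooled (D,))."""
    x = view_channels
    if x.ndim == 3 and x.shape[2] == model.config.in_channels:  # H, W, C
        x = x.transpose(2, 0, 1)
    maps, _ = model.encode(x[None].astype(np.float32))
    return maps[0], maps[0].mean(axis=(1, 2))


def attention_aggregate(model: MultiViewCNN, pooled_vectors) -> tuple[AttentionWeights, np.ndarray]:
    """Aggregate per-view descriptors into one convex mixture."""
    pooled = np.asarray(pooled_vectors, dtype=np.float32)
    if pooled.ndim != 2 or pooled.shape[0] == 0:
        raise ValueError("need at least one pooled view vector")
    p = model.params
    gate = np.tanh(pooled @ p["attn_U"]) * (
        1.0 / (1.0 + np.exp(-(pooled @ p["attn_V"])))
    )
    scores = gate @ p["attn_w"]
    attn = _softmax(scores[None, :], axis=1)[0]
    return AttentionWeights(attn), attn @ pooled


def classify(model: MultiViewCNN, aggregated: np.ndarray) -> ClassProbabilities:
    logits = np.asarray(aggregated, dtype=np.float32) @ model.params["head_w"].T
    logits = logits + model.params["head_b"]
    return ClassProbabilities(_softmax(logits[None])[0], logits)


def predict(
    mesh: TriangleMesh, viewset: ViewSet, model: MultiViewCNN
) -> tuple[int, ClassProbabilities, AttentionWeights]:
    """Full pipeline: normalize -> render -> encode -> attend -> classify."""
    arr = render_mesh_views(mesh, viewset, model.config.resolution)
    probs, attn = model.predict_views(arr)
    return probs.predicted_class, probs, attn


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            g = g.astype(params[k].dtype)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _class_weights(labels: np.ndarray, enabled: bool, n_classes: int = N_CLASSES) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    if not enabled:
        return np.ones(n_classes)
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = counts[present].sum() / (present.sum() * counts[present])
    return w


def train(
    views_train: np.ndarray,
    labels_train: np.ndarray,
    views_val: np.ndarray | None = None,
    labels_val: np.ndarray | None = None,
    config: TrainConfig | None = None,
) -> tuple[MultiViewCNN, list[dict]]:
    """Train on pre-rendered view tensors ``(N, V, C, H, W)``.

    Minimizes (optionally class-weighted) cross-entropy with Adam; early
    stops on validation loss with the configured patience, restoring the best
    parameters.  Returns the model and a per-epoch log.
    """
    config = config or TrainConfig()
    n, v = views_train.shape[:2]
    if n == 0:
        raise ValueError("empty training set")
    labels_train = np.asarray(labels_train, dtype=np.int64)
    missing = set(range(config.model.n_classes)) - set(labels_train.tolist())
    if missing:
        import warnings

        warnings.warn(f"classes absent from training split: {sorted(missing)}",
                      stacklevel=2)
    cw = _class_weights(labels_train, config.class_weighting, config.model.n_classes)

    model = MultiViewCNN(config.model, seed=config.seed)
    opt = _Adam(model.params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    log: list[dict] = []
    best_val = np.inf
    best_params = None
    since_best = 0

    for epoch in range(config.epochs):
        if config.cosine_decay and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            opt.lr = config.learning_rate * (
                0.1 + 0.45 * (1.0 + np.cos(np.pi * frac))
            )
        order = rng.permutation(n)
        total_loss = 0.0
        total_w = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = views_train[idx].reshape(-1, *views_train.shape[2:])
            if config.augment:
                xb = _augment_views(xb, rng, config.max_shift)
            yb = labels_train[idx]
            logits, _, (maps, enc_cache, head_cache) = model.forward(xb, v)
            probs = _softmax(logits, axis=1)
            wts = cw[yb]
            eps = 1e-12
            loss = -(wts * np.log(probs[np.arange(len(yb)), yb] + eps)).sum() / wts.sum()
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= (wts / wts.sum())[:, None]
            dmaps, grads = model.head_backward(dlogits.astype(np.float32), head_cache)
            grads.update(model.encoder_backward(dmaps, enc_cache))
            opt.step(model.params, grads)
            total_loss += loss * wts.sum()
            total_w += wts.sum()

        entry = {"epoch": epoch, "train_loss": float(total_loss / total_w)}
        if views_val is not None and len(views_val):
            val_loss, val_acc = _evaluate_loss(model, views_val, labels_val, cw)
            entry.update(val_loss=val_loss, val_accuracy=val_acc)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: p.copy() for k, p in model.params.items()}
                since_best = 0
            else:
                since_best += 1
        log.append(entry)
        if best_params is not None and since_best >= config.patience:
            break

    if best_params is not None:
        model.params = best_params
    return model, log


def _evaluate_loss(model, views, labels, cw) -> tuple[float, float]:
    labels = np.asarray(labels, dtype=np.int64)
    n, v = views.shape[:2]
    losses, correct, wsum = 0.0, 0, 0.0
    for start in range(0, n, 16):
        xb = views[start : start + 16].reshape(-1, *views.shape[2:])
        yb = labels[start : start + 16]
        logits, _, _ = model.forward(xb, v)
        probs = _softmax(logits, axis=1)
        wts = cw[yb]
        losses += -(wts * np.log(probs[np.arange(len(yb)), yb] + 1e-12)).sum()
        wsum += wts.sum()
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(losses / wsum), float(correct / n)
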