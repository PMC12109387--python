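"""Global-local attention segmentation network for dental point clouds.

Architecture, per cloud:

1. **Local branch** — each center's k-neighbor encoding rows pass through a
   shared point-wise MLP (linear → batch-norm → ReLU per layer) and are
   max-pooled over the neighborhood, giving a ``local_dim``-wide feature per
   center.
2. **Global branch** — the local features, projected to ``d_model``, feed a
   multi-head self-attention block (Q/K/V projections per head, scaled
   softmax affinities, value mixing) that captures long-range dependencies
   across the arch.
3. **Fusion** — per-center features (local ‖ attention) are summarized into a
   single global vector by attention pooling (learned softmax weights over
   centers) and soft pooling (channel-wise softmax-of-activations weighting);
   the global vector is broadcast and concatenated back onto every center.
4. **Head and decoder** — an MLP maps fused features to per-center features
   and class logits; per-point logits come from a feature-propagation
   decoder: inverse-distance interpolation of center features over the
   nearest centers, refined by a point-wise MLP that also sees the point's
   offset to its nearest center, its center distances, its position, and a
   mini max-pooled encoding of its own k-nearest-neighbor offsets.

Ablation switches reproduce the reduced variants: ``use_rel_encoding=False``
feeds absolute coordinates only, ``use_attention_pooling=False`` replaces the
learned pooling weights with an unweighted mean, and ``use_transformer=False``
drops the attention branch entirely.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Parameter, Tensor, concat, log_softmax, softmax
from .io_formats import LabeledCloud
from .preprocess import ENCODING_LAYOUTS, preprocess_cloud, relative_encoding

__all__ = [
    "ModelConfig",
    "SegmentationOutput",
    "SegModel",
    "Linear",
    "BatchNorm1d",
    "LocalFeatureExtractor",
    "MultiHeadSelfAttention",
    "AttentionPool",
    "soft_pool",
    "fuse",
    "cross_entropy_loss",
    "cross_entropy_from_logits",
    "interpolate_to_points",
    "nearest_centers",
    "save_checkpoint",
    "load_checkpoint",
]


# --------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    Defaults follow the full-scale design: 2048 FPS centers with 64-point
    neighborhoods, 128-d local features, 8 attention heads of 32 dims
    (d_model = 256) and 33 output classes (gingiva + 32 FDI teeth).
    """

    num_centers: int = 2048
    k: int = 64
    local_dim: int = 128
    attn_heads: int = 8
    head_dim: int = 32
    num_classes: int = 33
    mlp_hidden: tuple[int, ...] = (32, 64, 128)
    head_hidden: tuple[int, ...] = (256, 128)
    refine_hidden: tuple[int, ...] = (128,)
    point_knn: int = 8
    point_mlp: tuple[int, ...] = (32,)
    upsample_neighbors: int = 3
    encoding_layout: str = "rel_dist_abs"
    scale_mode: str = "sqrt_dhead"  # or "dmodel": literal divisor d_model
    use_rel_encoding: bool = True
    use_attention_pooling: bool = True
    use_transformer: bool = True

    def __post_init__(self) -> None:
        self.mlp_hidden = tuple(self.mlp_hidden)
        self.head_hidden = tuple(self.head_hidden)
        self.refine_hidden = tuple(self.refine_hidden)
        self.point_mlp = tuple(self.point_mlp)
        if self.mlp_hidden[-1] != self.local_dim:
            raise ValueError("mlp_hidden[-1] must equal local_dim")
        if self.scale_mode not in ("sqrt_dhead", "dmodel"):
            raise ValueError("scale_mode must be 'sqrt_dhead' or 'dmodel'")
        if self.encoding_layout not in ENCODING_LAYOUTS:
            raise ValueError(f"unknown encoding_layout {self.encoding_layout!r}")

    @property
    def d_model(self) -> int:
        return self.attn_heads * self.head_dim

    @property
    def effective_layout(self) -> str:
        """Encoding layout after the relative-encoding ablation switch."""
        return self.encoding_layout if self.use_rel_encoding else "abs_only"

    @property
    def feature_width(self) -> int:
        return ENCODING_LAYOUTS[self.effective_layout]

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        """Half-width model on 256 centers / 16 neighbors for CPU training."""
        base = dict(
            num_centers=256,
            k=16,
            local_dim=64,
            attn_heads=8,
            head_dim=16,
            mlp_hidden=(16, 32, 64),
            head_hidden=(128, 64),
            refine_hidden=(64,),
            point_mlp=(16,),
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class SegmentationOutput:
    """Per-point class distribution and argmax labels."""

    probabilities: np.ndarray  # (N, C), rows sum to 1
    labels: np.ndarray  # (N,) argmax, lowest-index tie-break
    center_indices: np.ndarray  # (m,) centers used for this prediction


# --------------------------------------------------------------------------
# layers


class Module:
    """Tiny module base: recursive parameter/buffer discovery + train flag."""

    training: bool = True

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Module):
                out.extend(val.named_buffers(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_buffers(f"{key}.{i}."))
            elif name.startswith("running_") and isinstance(val, np.ndarray):
                out.append((key, val))
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for val in vars(self).values():
            if isinstance(val, Module):
                val.set_training(flag)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.set_training(flag)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        # Kaiming-uniform fan-in init, suited to the ReLU MLP stacks
        bound = math.sqrt(6.0 / in_dim)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm1d(Module):
    """Feature-wise batch normalization over the leading axes.

    Training mode normalizes with batch statistics and updates running
    estimates; evaluation mode uses the running statistics only, so
    single-cloud inference never depends on batch composition.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        flat = x.reshape(-1, x.shape[-1])
        if self.training:
            # fused forward/backward: one graph node instead of an op chain
            n = flat.shape[0]
            mu = flat.data.mean(axis=0)
            var = flat.data.var(axis=0)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (flat.data - mu) * inv
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (
                var * (n / max(n - 1, 1)) - self.running_var
            )
            gamma, beta = self.gamma, self.beta
            out_data = gamma.data * xhat + beta.data

            def bw(g: np.ndarray) -> None:
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=0))
                if gamma.requires_grad:
                    gamma._accumulate((g * xhat).sum(axis=0))
                if flat.requires_grad:
                    gx = g * gamma.data
                    flat._accumulate(
                        inv
                        * (
                            gx
                            - gx.mean(axis=0)
                            - xhat * (gx * xhat).mean(axis=0)
                        )
                    )

            norm = Tensor(out_data, parents=(flat, gamma, beta), backward=bw)
            return norm.reshape(x.shape)
        norm = (flat - Tensor(self.running_mean)) / Tensor(
            np.sqrt(self.running_var + self.eps)
        )
        return (norm * self.gamma + self.beta).reshape(x.shape)


class LocalFeatureExtractor(Module):
    """Shared point-wise MLP over neighbor encodings + neighborhood max-pool."""

    def __init__(self, in_dim: int, widths: tuple[int, ...], rng: np.random.Generator):
        self.layers: list[Linear] = []
        self.norms: list[BatchNorm1d] = []
        prev = in_dim
        for w in widths:
            self.layers.append(Linear(prev, w, rng, bias=False))
            self.norms.append(BatchNorm1d(w))
            prev = w

    def __call__(self, encoding: Tensor) -> Tensor:
        """(m, k, F) neighbor features -> (m, local_dim) per-center features."""
        m, k, f = encoding.shape
        h = encoding.reshape(m * k, f)
        for lin, bn in zip(self.layers, self.norms):
            h = bn(lin(h)).relu()
        return h.reshape(m, k, -1).max(axis=1)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over center tokens, 8 heads default."""

    def __init__(self, d_model: int, heads: int, head_dim: int,
                 rng: np.random.Generator, scale_mode: str = "sqrt_dhead"):
        if heads * head_dim != d_model:
            raise ValueError("heads * head_dim must equal d_model")
        self.heads = heads
        self.head_dim = head_dim
        self.d_model = d_model
        self.scale = math.sqrt(head_dim) if scale_mode == "sqrt_dhead" else float(d_model)
        bound = math.sqrt(6.0 / d_model)
        self.w_q = Parameter(rng.uniform(-bound, bound, size=(d_model, d_model)))
        self.w_k = Parameter(rng.uniform(-bound, bound, size=(d_model, d_model)))
        self.w_v = Parameter(rng.uniform(-bound, bound, size=(d_model, d_model)))

    def _split(self, t: Tensor, m: int) -> Tensor:
        # (m, d_model) -> (heads, m, head_dim)
        return t.reshape(m, self.heads, self.head_dim).transpose((1, 0, 2))

    def attention_matrices(self, x: Tensor) -> np.ndarray:
        """Row-stochastic affinity matrices A, one (m, m) per head."""
        _, a = self._forward(x)
        return a

    def _forward(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        m = x.shape[0]
        q = self._split(x @ self.w_q, m)
        k = self._split(x @ self.w_k, m)
        v = self._split(x @ self.w_v, m)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / self.scale)
        a = softmax(scores, axis=-1)  # (heads, m, m), rows sum to 1
        z = a @ v  # (heads, m, head_dim)
        z = z.transpose((1, 0, 2)).reshape(m, self.d_model)
        return z, a.data

    def __call__(self, x: Tensor) -> Tensor:
        z, _ = self._forward(x)
        return z


class AttentionPool(Module):
    """Learned softmax weighting over feature vectors: f = Σ_i α_i x_i.

    Scores are a scalar linear map of each vector; softmax over the set turns
    them into weights α that sum to 1.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        bound = math.sqrt(6.0 / dim)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(dim, 1)))

    def weights(self, x: Tensor) -> Tensor:
        scores = x @ self.weight  # (n, 1)
        return softmax(scores, axis=0)

    def __call__(self, x: Tensor) -> Tensor:
        alpha = self.weights(x)  # (n, 1)
        return (alpha * x).sum(axis=0)  # (d,)


def soft_pool(x: Tensor) -> Tensor:
    """Channel-wise softmax-of-activations aggregation (SoftPool scheme).

    For each channel c: F[c] = Σ_i softmax_i(x_ic) · x_ic, i.e. activations
    weight themselves exponentially; dominated by large activations but
    smoother than a hard max.  Max-subtraction guards overflow.
    """
    w = softmax(x, axis=0)  # (m, d), columns sum to 1
    return (w * x).sum(axis=0)


def fuse(f_local: Tensor, f_global: Tensor) -> Tensor:
    """Concat per-center local features with the broadcast global vector.

    Order is fixed as (local, global); output width is the sum of widths.
    """
    m = f_local.shape[0]
    tiled = Tensor(np.zeros((m, f_global.shape[-1]))) + f_global.reshape(1, -1)
    return concat([f_local, tiled], axis=1)


# --------------------------------------------------------------------------
# the model


class SegModel(Module):
    """End-to-end center-level network with a per-point interpolation decoder."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f_in = config.feature_width
        self.local = LocalFeatureExtractor(f_in, config.mlp_hidden, rng)
        per_center = config.local_dim
        if config.use_transformer:
            self.proj = Linear(config.local_dim, config.d_model, rng)
            self.attention = MultiHeadSelfAttention(
                config.d_model, config.attn_heads, config.head_dim, rng,
                scale_mode=config.scale_mode,
            )
            per_center += config.d_model
        if config.use_attention_pooling:
            self.attn_pool = AttentionPool(per_center, rng)
        self.per_center_dim = per_center
        self.fusion_dim = per_center + 2 * per_center  # local + (attn ‖ soft) global
        self.head_layers: list[Linear] = []
        self.head_norms: list[BatchNorm1d] = []
        prev = self.fusion_dim
        for w in config.head_hidden:
            self.head_layers.append(Linear(prev, w, rng, bias=False))
            self.head_norms.append(BatchNorm1d(w))
            prev = w
        self.penult_dim = prev
        self.head_out = Linear(prev, config.num_classes, rng)
        # feature-propagation decoder: interpolated center feature + point
        # geometry (offset to nearest center, center distances, position) +
        # a mini point-local encoder over each point's own k-NN offsets
        self.point_layers: list[Linear] = []
        self.point_norms: list[BatchNorm1d] = []
        pprev = 4  # [offset to neighbor (3), distance (1)]
        for w in config.point_mlp:
            self.point_layers.append(Linear(pprev, w, rng, bias=False))
            self.point_norms.append(BatchNorm1d(w))
            pprev = w
        self.refine_layers: list[Linear] = []
        self.refine_norms: list[BatchNorm1d] = []
        rprev = prev + 3 + config.upsample_neighbors + 3 + pprev
        for w in config.refine_hidden:
            self.refine_layers.append(Linear(rprev, w, rng, bias=False))
            self.refine_norms.append(BatchNorm1d(w))
            rprev = w
        self.refine_out = Linear(rprev, config.num_classes, rng)

    # -- forward -----------------------------------------------------------
    def center_logits(self, encoding_features: np.ndarray) -> Tensor:
        """(m, k, F) neighbor encodings -> (m, C) center class logits."""
        return self.head_out(self.center_features(encoding_features))

    def center_features(self, encoding_features: np.ndarray) -> Tensor:
        """(m, k, F) neighbor encodings -> (m, penult_dim) fused features."""
        cfg = self.config
        if encoding_features.shape[-1] != cfg.feature_width:
            raise ValueError(
                f"encoding feature width {encoding_features.shape[-1]} does not "
                f"match configured layout {cfg.effective_layout!r} "
                f"(F={cfg.feature_width})"
            )
        x = Tensor(encoding_features)
        local = self.local(x)  # (m, local_dim)
        if cfg.use_transformer:
            z = self.attention(self.proj(local))  # (m, d_model)
            per_center = concat([local, z], axis=1)
        else:
            per_center = local
        if cfg.use_attention_pooling:
            pooled = self.attn_pool(per_center)
        else:
            pooled = per_center.mean(axis=0)  # ablation: unweighted mean
        global_vec = concat([pooled, soft_pool(per_center)], axis=0)
        fused = fuse(per_center, global_vec)
        h = fused
        for lin, bn in zip(self.head_layers, self.head_norms):
            h = bn(lin(h)).relu()
        return h  # (m, penult_dim)

    def point_local_features(self, neighbor_offsets: np.ndarray) -> Tensor:
        """Mini point-local encoder: (n, k', 3) own-neighborhood offsets ->
        (n, point_mlp[-1]) via a shared MLP on [offset, distance] rows and a
        max-pool over the k' neighbors."""
        n, kk, _ = neighbor_offsets.shape
        d = np.linalg.norm(neighbor_offsets, axis=2, keepdims=True)
        h = Tensor(
            np.concatenate([neighbor_offsets, d], axis=2).reshape(n * kk, 4)
        )
        for lin, bn in zip(self.point_layers, self.point_norms):
            h = bn(lin(h)).relu()
        return h.reshape(n, kk, -1).max(axis=1)

    def decode_points(
        self,
        center_feats: Tensor,
        centers_xyz: np.ndarray,
        points: np.ndarray,
        order: np.ndarray,
        dist: np.ndarray,
        neighbor_offsets: np.ndarray,
    ) -> Tensor:
        """Per-point class logits via feature propagation.

        Center features are inverse-distance interpolated over each point's
        ``upsample_neighbors`` nearest centers (``order``/``dist``), then a
        point-wise MLP refines the interpolated feature together with the
        point's offset to its nearest center, its center distances, its
        absolute position, and a mini encoding of its own k'-neighborhood —
        recovering sub-cell boundary detail (e.g. the gingival margin) that
        interpolation alone cannot express.
        """
        w = 1.0 / (dist + 1e-8)
        w /= w.sum(axis=1, keepdims=True)
        gathered = center_feats.take(order, axis=0)  # (n, u, penult)
        interp = (gathered * Tensor(w[..., None])).sum(axis=1)
        offset = points - centers_xyz[order[:, 0]]
        extra = Tensor(np.concatenate([offset, dist, points], axis=1))
        local = self.point_local_features(neighbor_offsets)
        h = concat([interp, extra, local], axis=1)
        for lin, bn in zip(self.refine_layers, self.refine_norms):
            h = bn(lin(h)).relu()
        return self.refine_out(h)  # (n, C)

    # -- inference ---------------------------------------------------------
    def segment(
        self,
        cloud: LabeledCloud,
        center_indices: np.ndarray | None = None,
    ) -> SegmentationOutput:
        """Predict a class distribution for every point of a normalized cloud.

        Centers are re-selected by FPS unless ``center_indices`` is given
        (useful for equivariance checks and cached preprocessing).
        """
        if len(cloud) < 1:
            raise ValueError("empty cloud")
        cfg = self.config
        pts = cloud.points
        if center_indices is None:
            sampling, enc = preprocess_cloud(
                pts, cfg.num_centers, cfg.k, layout=cfg.effective_layout
            )
            center_indices = sampling.center_indices
        else:
            center_indices = np.asarray(center_indices, dtype=np.int64)
            from .preprocess import knn_group  # local import to avoid cycle noise

            neigh = knn_group(pts, center_indices, min(cfg.k, len(pts)))
            enc = relative_encoding(pts, center_indices, neigh, cfg.effective_layout)
        was_training = self.training
        self.set_training(False)
        try:
            feats = self.center_features(enc.features)
            centers_xyz = pts[center_indices]
            u = min(cfg.upsample_neighbors, len(center_indices))
            order, dist = nearest_centers(pts, centers_xyz, u)
            from .preprocess import knn_group

            pn = knn_group(pts, np.arange(len(pts)), min(cfg.point_knn, len(pts)))
            offsets = pts[pn] - pts[:, None, :]
            point_logits = self.decode_points(
                feats, centers_xyz, pts, order, dist, offsets
            ).data
        finally:
            self.set_training(was_training)
        shift = point_logits - point_logits.max(axis=1, keepdims=True)
        e = np.exp(shift)
        probs = e / e.sum(axis=1, keepdims=True)
        return SegmentationOutput(
            probabilities=probs,
            labels=np.argmax(probs, axis=1),
            center_indices=center_indices,
        )


def nearest_centers(
    points: np.ndarray,
    centers_xyz: np.ndarray,
    u: int,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of each point's ``u`` nearest centers.

    Stable sort gives lowest-index tie-breaks; chunking bounds memory.
    """
    points = np.asarray(points)
    if points.dtype != np.float32:
        points = points.astype(np.float64)
    n = len(points)
    order = np.empty((n, u), dtype=np.int64)
    dist = np.empty((n, u))
    csq = np.einsum("ij,ij->i", centers_xyz, centers_xyz)
    for lo in range(0, n, chunk):
        p = points[lo : lo + chunk]
        d2 = (
            np.einsum("ij,ij->i", p, p)[:, None]
            + csq[None, :]
            - 2.0 * (p @ centers_xyz.T)
        )
        np.maximum(d2, 0.0, out=d2)
        o = np.argsort(d2, axis=1, kind="stable")[:, :u]
        order[lo : lo + chunk] = o
        dist[lo : lo + chunk] = np.sqrt(np.take_along_axis(d2, o, axis=1))
    return order, dist


def interpolate_to_points(
    points: np.ndarray,
    centers: np.ndarray,
    center_values: np.ndarray,
    n_neighbors: int = 3,
    chunk: int = 4096,
) -> np.ndarray:
    """Inverse-distance interpolation of per-center values onto points.

    Weights are 1/(d + 1e-8) over the ``n_neighbors`` nearest centers,
    normalized per point; a point coinciding with a center takes that
    center's value exactly.
    """
    points = np.asarray(points, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    u = min(n_neighbors, len(centers))
    out = np.empty((len(points), center_values.shape[1]))
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk]
        d2 = np.sum((p[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        order = np.argsort(d2, axis=1, kind="stable")[:, :u]
        d = np.sqrt(np.take_along_axis(d2, order, axis=1))
        w = 1.0 / (d + 1e-8)
        exact = d[:, 0] < 1e-12  # coincident with a center
        w /= w.sum(axis=1, keepdims=True)
        vals = center_values[order]  # (chunk, u, C)
        block = np.einsum("nu,nuc->nc", w, vals)
        block[exact] = center_values[order[exact, 0]]
        out[lo : lo + chunk] = block
    return out


# --------------------------------------------------------------------------
# losses


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean point-wise cross entropy, −(1/N) Σ log p at the true class.

    Probabilities are clamped at 1e-12 inside the log.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64).reshape(-1)
    if probabilities.ndim != 2 or len(probabilities) != len(labels):
        raise ValueError(
            f"shape mismatch: probabilities {probabilities.shape} vs "
            f"{len(labels)} labels"
        )
    if labels.min() < 0 or labels.max() >= probabilities.shape[1]:
        raise ValueError("labels out of range")
    p = probabilities[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p, 1e-12))))


def cross_entropy_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean cross entropy straight from logits (log-softmax)."""
    labels = np.asarray(labels, dtype=np.int64).reshape(-1)
    n, c = logits.shape
    if len(labels) != n:
        raise ValueError("shape mismatch between logits and labels")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    return -(log_softmax(logits, axis=1) * Tensor(onehot)).sum() * (1.0 / n)


# --------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: SegModel, path: str | Path) -> None:
    """Single-file archive: config JSON + named weights and running stats."""
    arrays = {f"param:{k}": p.data for k, p in model.named_parameters()}
    arrays.update({f"buffer:{k}": b for k, b in model.named_buffers()})
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> SegModel:
    with np.load(path) as archive:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(archive["config_json"].tolist()).decode())
        )
        model = SegModel(cfg)
        params = dict(model.named_parameters())
        for key in archive.files:
            if key.startswith("param:"):
                params[key[6:]].data[...] = archive[key]
        buffers = dict(model.named_buffers())
        for key in archive.files:
            if key.startswith("buffer:"):
                buffers[key[7:]][...] = archive[key]
    return model
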