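"""Training loop: augmentation, Adam, early stopping on validation mIoU.

Training operates on normalized clouds (coordinates in [-1, 1]).  Because the
augmentations are a z-rotation, an isotropic scale and a translation, FPS
center selection and k-NN neighborhoods are invariant under them — both
depend only on distance *rankings* — so each cloud's centers and neighbor
indices are computed once and cached; only the relative encoding is refreshed
from the augmented coordinates each epoch.

The per-point cross-entropy is evaluated on a random subsample of points per
cloud per step, backpropagated through the feature-propagation decoder onto
the whole network.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .io_formats import LabeledCloud
from .metrics import ConfusionMatrix, compute_metrics
from .network import (
    ModelConfig,
    SegModel,
    cross_entropy_from_logits,
    cross_entropy_loss,
    nearest_centers,
)
from .preprocess import farthest_point_sampling, knn_group, relative_encoding

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainResult", "augment", "train", "split_dataset",
           "write_history_csv", "Adam"]


@dataclass
class TrainConfig:
    """Optimization and augmentation settings.

    Defaults mirror the full-scale protocol (Adam at 1e-4, batch 16, up to
    200 epochs, early stopping); desk-scale runs typically override
    ``learning_rate`` and ``max_epochs``.
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 200
    early_stop_patience: int = 20
    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_range: tuple[float, float] = (-0.05, 0.05)
    full_3d_rotation: bool = False
    augment: bool = True
    points_supervised: int = 1024
    lr_schedule: str = "constant"  # or "cosine": decay to 3% of the base rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        for lo, hi, default in (
            (*self.rotation_deg, 0.0),
            (*self.scale_range, 1.0),
            (*self.translation_range, 0.0),
        ):
            if not lo <= default <= hi:
                raise ValueError("augmentation ranges must contain their identity value")


@dataclass
class TrainResult:
    model: SegModel
    history: list[dict]
    best_epoch: int
    best_val_miou: float


# --------------------------------------------------------------------------
# augmentation


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation_uniform(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform 3D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def augment(
    cloud: LabeledCloud,
    config: TrainConfig,
    rng: np.random.Generator | int | None = None,
) -> LabeledCloud:
    """Rotate (z-axis) → scale → translate, with ranges from ``config``.

    Labels and point count are untouched; deterministic for a seeded ``rng``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    angle = np.deg2rad(rng.uniform(*config.rotation_deg))
    rot = _rotation_uniform(rng) if config.full_3d_rotation else _rotation_z(angle)
    scale = rng.uniform(*config.scale_range)
    shift = rng.uniform(*config.translation_range, size=3)
    pts = cloud.points @ rot.T * scale + shift
    return LabeledCloud(
        pts,
        labels=None if cloud.labels is None else cloud.labels.copy(),
        class_count=cloud.class_count,
    )


# --------------------------------------------------------------------------
# optimizer


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# data plumbing


def split_dataset(
    clouds: list, ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Seeded shuffle + 70/15/15 (by default) train/val/test split."""
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("split ratios must sum to 1")
    idx = np.random.default_rng(seed).permutation(len(clouds))
    n_train = int(round(ratios[0] * len(clouds)))
    n_val = int(round(ratios[1] * len(clouds)))
    take = lambda sl: [clouds[i] for i in sl]
    return take(idx[:n_train]), take(idx[n_train:n_train + n_val]), take(idx[n_train + n_val:])


class _PreparedCloud:
    """Cached FPS centers and k-NN indices (augmentation-invariant)."""

    def __init__(self, cloud: LabeledCloud, model_config: ModelConfig,
                 compute_dtype=np.float32):
        self.cloud = cloud
        n = len(cloud)
        m = min(model_config.num_centers, n)
        pts = cloud.points.astype(compute_dtype, copy=False)
        self.centers = farthest_point_sampling(pts, m).center_indices
        self.neighbors = knn_group(pts, self.centers, min(model_config.k, n))
        # point -> nearest-center interpolation structure; invariant under the
        # augmentation family (rigid motion + uniform scale preserves rankings
        # and scales all distances equally, leaving normalized weights fixed)
        u = min(model_config.upsample_neighbors, m)
        self.interp_order, self.interp_dist = nearest_centers(
            pts, pts[self.centers], u
        )
        # each point's own neighborhood for the decoder's mini local encoder
        self.point_neighbors = knn_group(
            pts, np.arange(n), min(model_config.point_knn, n)
        )


def _forward_loss(
    model: SegModel,
    prep: _PreparedCloud,
    points: np.ndarray,
    rng: np.random.Generator,
    n_supervised: int,
) -> Tensor:
    """Differentiable per-point cross entropy on a point subsample."""
    enc = relative_encoding(
        points, prep.centers, prep.neighbors, model.config.effective_layout
    )
    feats = model.center_features(enc.features)  # (m, penult) Tensor
    n = len(points)
    if n_supervised < n:
        sub = rng.choice(n, size=n_supervised, replace=False)
    else:
        sub = np.arange(n)
    order = prep.interp_order[sub]  # rankings are augmentation-invariant
    sub_pts = points[sub]
    centers_xyz = points[prep.centers]
    dist = np.linalg.norm(sub_pts[:, None, :] - centers_xyz[order], axis=2)
    offsets = points[prep.point_neighbors[sub]] - sub_pts[:, None, :]
    point_logits = model.decode_points(
        feats, centers_xyz, sub_pts, order, dist, offsets
    )
    return cross_entropy_from_logits(point_logits, prep.cloud.labels[sub])


def evaluate(
    model: SegModel, prepared: list[_PreparedCloud]
) -> tuple[float, float]:
    """(mean per-point cross entropy, mIoU) over a list of prepared clouds."""
    cm = ConfusionMatrix(model.config.num_classes)
    losses = []
    was_training = model.training
    model.set_training(False)
    try:
        for prep in prepared:
            enc = relative_encoding(
                prep.cloud.points, prep.centers, prep.neighbors,
                model.config.effective_layout,
            )
            feats = model.center_features(enc.features)
            pts = prep.cloud.points
            offsets = pts[prep.point_neighbors] - pts[:, None, :]
            point_logits = model.decode_points(
                feats, pts[prep.centers], pts,
                prep.interp_order, prep.interp_dist, offsets,
            ).data
            shift = point_logits - point_logits.max(axis=1, keepdims=True)
            e = np.exp(shift)
            probs = e / e.sum(axis=1, keepdims=True)
            cm.accumulate(np.argmax(probs, axis=1), prep.cloud.labels)
            losses.append(cross_entropy_loss(probs, prep.cloud.labels))
    finally:
        model.set_training(was_training)
    return float(np.mean(losses)), compute_metrics(cm).mean_iou


# --------------------------------------------------------------------------
# the loop


def train(
    train_clouds: list[LabeledCloud],
    val_clouds: list[LabeledCloud],
    model_config: ModelConfig,
    train_config: TrainConfig,
    model: SegModel | None = None,
    prepared: tuple[list, list] | None = None,
) -> TrainResult:
    """Minimize mean cross entropy with Adam; early-stop on validation mIoU.

    Stops when validation mIoU has not improved for ``early_stop_patience``
    epochs (or at ``max_epochs``) and restores the best-validation weights.
    Fully reproducible for a fixed seed.
    """
    if not train_clouds:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 0x7214]))
    if model is None:
        model = SegModel(model_config, seed=int(rng.integers(2**31)))
    if prepared is None:
        prep_train = [_PreparedCloud(c, model_config) for c in train_clouds]
        prep_val = [_PreparedCloud(c, model_config) for c in val_clouds]
    else:
        prep_train, prep_val = prepared
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    history: list[dict] = []
    best_miou = -np.inf
    best_epoch = -1
    best_state: list[np.ndarray] | None = None
    best_buffers: list[np.ndarray] | None = None
    since_improve = 0
    for epoch in range(train_config.max_epochs):
        if train_config.lr_schedule == "cosine":
            frac = epoch / max(train_config.max_epochs - 1, 1)
            floor = 0.03 * train_config.learning_rate
            optimizer.lr = floor + 0.5 * (train_config.learning_rate - floor) * (
                1.0 + np.cos(np.pi * frac)
            )
        model.set_training(True)
        order = rng.permutation(len(prep_train))
        epoch_losses = []
        for lo in range(0, len(order), train_config.batch_size):
            batch = order[lo : lo + train_config.batch_size]
            optimizer.zero_grad()
            batch_losses = []
            for ci in batch:
                prep = prep_train[ci]
                if train_config.augment:
                    pts = augment(prep.cloud, train_config, rng).points
                else:
                    pts = prep.cloud.points
                loss = _forward_loss(
                    model, prep, pts, rng, train_config.points_supervised
                )
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, cloud {ci}: {loss.data}"
                    )
                loss.backward(np.asarray(1.0 / len(batch)))
                batch_losses.append(float(loss.data))
            optimizer.step()
            epoch_losses.extend(batch_losses)
        model.set_training(False)
        val_loss, val_miou = (np.nan, np.nan) if not prep_val else evaluate(model, prep_val)
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_miou": val_miou,
        }
        history.append(record)
        logger.info(
            "epoch %3d train_loss=%.4f val_loss=%.4f val_mIoU=%.4f",
            epoch, record["train_loss"], val_loss, val_miou,
        )
        monitored = val_miou if prep_val else -record["train_loss"]
        if monitored > best_miou:
            best_miou = monitored
            best_epoch = epoch
            best_state = [p.data.copy() for p in model.parameters()]
            best_buffers = [b.copy() for _, b in model.named_buffers()]
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= train_config.early_stop_patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break
    if best_state is not None:
        for p, w in zip(model.parameters(), best_state):
            p.data[...] = w
        for (_, b), w in zip(model.named_buffers(), best_buffers):
            b[...] = w
    return TrainResult(
        model=model,
        history=history,
        best_epoch=best_epoch,
        best_val_miou=float(best_miou) if prep_val else float("nan"),
    )


def write_history_csv(history: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "train_loss", "val_loss", "val_miou"]
        )
        writer.writeheader()
        writer.writerows(history)
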