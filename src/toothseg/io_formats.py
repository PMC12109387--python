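"""Mesh / labeled-point-cloud I/O and coordinate normalization.

Intraoral scanners emit triangular surface meshes (STL/PLY/OBJ); the
segmentation pipeline consumes point clouds with one integer class label per
point.  This module covers the conversions between the two and the explicit
[-1, 1] coordinate normalization applied before any model sees the data.

Labels use a dense internal scheme: class 0 is gingiva and classes 1..32 are
the 32 permanent teeth in fixed FDI order (11-18, 21-28, 31-38, 41-48).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "Mesh",
    "LabeledCloud",
    "LabelScheme",
    "NormalizeTransform",
    "FormatError",
    "GeometryError",
    "LabelValidationError",
    "read_mesh",
    "sample_surface",
    "mesh_vertices_as_cloud",
    "normalize_cloud",
    "read_labeled_cloud",
    "write_labeled_cloud",
]


class FormatError(ValueError):
    """Unreadable or unrecognized file format."""


class GeometryError(ValueError):
    """Degenerate geometry (e.g. a mesh with zero total surface area)."""


class LabelValidationError(ValueError):
    """Per-point labels outside the configured class range."""


# --------------------------------------------------------------------------
# label bookkeeping


#: FDI two-digit codes in the fixed internal order; class index = position + 1.
FDI_ORDER: tuple[int, ...] = tuple(
    10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9)
)


@dataclass(frozen=True)
class LabelScheme:
    """33-class labeling: gingiva (0) + 32 FDI permanent teeth (1..32).

    ``tooth_type`` merges the four quadrant instances of each tooth position
    into one of T1..T8 (central incisor .. third molar); class 0 maps to
    "gum".  This is the aggregation used for per-tooth-type reporting.
    """

    num_classes: int = 33

    @property
    def fdi_codes(self) -> tuple[int, ...]:
        return FDI_ORDER

    def class_of_fdi(self, fdi: int) -> int:
        return FDI_ORDER.index(fdi) + 1

    def fdi_of_class(self, cls: int) -> int:
        if cls == 0:
            raise ValueError("class 0 is gingiva, not a tooth")
        return FDI_ORDER[cls - 1]

    def tooth_type(self, cls: int) -> str:
        if cls == 0:
            return "gum"
        return f"T{FDI_ORDER[cls - 1] % 10}"

    @property
    def type_names(self) -> tuple[str, ...]:
        return ("gum",) + tuple(f"T{i}" for i in range(1, 9))

    def type_index(self, cls: int) -> int:
        """Map a class to its merged-group index (0=gum, 1..8 = T1..T8)."""
        return 0 if cls == 0 else FDI_ORDER[cls - 1] % 10


# --------------------------------------------------------------------------
# core containers


@dataclass
class Mesh:
    """Triangular surface mesh in scanner units (mm)."""

    vertices: np.ndarray  # (M, 3) float
    faces: np.ndarray  # (T, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass
class LabeledCloud:
    """Point cloud with per-point class labels; the pipeline's exchange object.

    ``labels`` may be None for unlabeled clouds (e.g. fresh mesh samples
    awaiting prediction).
    """

    points: np.ndarray  # (N, 3) float
    labels: np.ndarray | None = None  # (N,) int in [0, class_count)
    normals: np.ndarray | None = None  # (N, 3) unit vectors
    class_count: int = 33

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 1:
            raise ValueError("cloud must contain at least one point")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
            if len(self.labels) != len(self.points):
                raise ValueError("labels length must match point count")
            bad = np.flatnonzero(
                (self.labels < 0) | (self.labels >= self.class_count)
            )
            if bad.size:
                raise LabelValidationError(
                    f"labels out of range [0, {self.class_count}) at indices "
                    f"{bad[:20].tolist()}"
                )
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit vectors (|n| = 1 ± 1e-6)")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class NormalizeTransform:
    """Affine map applied by :func:`normalize_cloud`: x' = (x - centroid)/scale."""

    centroid: np.ndarray
    scale: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.centroid) / self.scale

    def invert(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) * self.scale + self.centroid


# --------------------------------------------------------------------------
# mesh ingestion


def read_mesh(path: str | Path) -> Mesh:
    """Read an STL/PLY/OBJ surface mesh; degenerate faces are dropped.

    A face is degenerate when its three vertex indices are not distinct.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        loaded = trimesh.load(str(path), force="mesh")
    except Exception as exc:
        raise FormatError(
            f"cannot parse {path} (extension {path.suffix!r}): {exc}"
        ) from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise FormatError(
            f"{path} (extension {path.suffix!r}) did not contain a triangular mesh"
        )
    faces = np.asarray(loaded.faces, dtype=np.int64)
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    dropped = int((~distinct).sum())
    if dropped:
        logger.info("dropped %d degenerate faces from %s", dropped, path)
    return Mesh(np.asarray(loaded.vertices, dtype=np.float64), faces[distinct])


def sample_surface(mesh: Mesh, n_points: int, seed: int = 0) -> LabeledCloud:
    """Draw ``n_points`` area-uniform samples from the mesh surface.

    Triangles are selected with probability proportional to their area and
    points placed barycentric-uniformly within each; fully deterministic for
    a fixed ``seed``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    areas = mesh.face_areas
    total = areas.sum()
    if total <= 0:
        raise GeometryError("mesh has zero total surface area")
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    pts, _ = trimesh.sample.sample_surface(tm, n_points, seed=int(seed))
    return LabeledCloud(np.asarray(pts, dtype=np.float64), labels=None)


def mesh_vertices_as_cloud(mesh: Mesh) -> LabeledCloud:
    """Shortcut: use mesh vertices directly as the point cloud (no resampling)."""
    return LabeledCloud(mesh.vertices.copy(), labels=None)


# --------------------------------------------------------------------------
# normalization


def normalize_cloud(cloud: LabeledCloud) -> tuple[LabeledCloud, NormalizeTransform]:
    """Center at the centroid, then isotropically scale into [-1, 1]^3.

    The scale is the maximum absolute coordinate after centering, so the
    extremal coordinate lands exactly on ±1.  Isotropic scaling preserves
    shape (and hence neighbor distances up to a common factor).  A cloud of
    identical points maps to the origin with scale 1.
    """
    centroid = cloud.points.mean(axis=0)
    centered = cloud.points - centroid
    scale = float(np.max(np.abs(centered)))
    if scale == 0.0:
        scale = 1.0
    out = LabeledCloud(
        centered / scale,
        labels=None if cloud.labels is None else cloud.labels.copy(),
        normals=None if cloud.normals is None else cloud.normals.copy(),
        class_count=cloud.class_count,
    )
    return out, NormalizeTransform(centroid=centroid, scale=scale)


# --------------------------------------------------------------------------
# labeled cloud I/O


def write_labeled_cloud(cloud: LabeledCloud, path: str | Path) -> None:
    """Write a labeled cloud as ASCII PLY (vertex property "label") or xyz text.

    The format is chosen from the extension: ``.ply`` → PLY, anything else →
    whitespace text with one ``x y z label`` record per line.  Coordinates are
    stored as 32-bit floats in both formats.
    """
    path = Path(path)
    labels = cloud.labels
    if path.suffix.lower() == ".ply":
        pc = trimesh.PointCloud(cloud.points.astype(np.float32))
        if labels is not None:
            pc.vertex_attributes = {"label": labels.astype(np.int32)}
        data = pc.export(file_type="ply", encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        pts = cloud.points.astype(np.float32)
        if labels is None:
            np.savetxt(path, pts, fmt="%.9g")
        else:
            with open(path, "w") as fh:
                for (x, y, z), lab in zip(pts, labels):
                    fh.write(f"{x:.9g} {y:.9g} {z:.9g} {int(lab)}\n")


def read_labeled_cloud(
    path: str | Path,
    class_count: int = 33,
    allow_unlabeled: bool = False,
) -> LabeledCloud:
    """Read a labeled cloud written by :func:`write_labeled_cloud`.

    PLY files carry the label in an integer per-vertex property "label";
    text files carry it as the fourth whitespace-separated column.  Labels
    outside ``[0, class_count)`` raise :class:`LabelValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".ply":
        try:
            loaded = trimesh.load(str(path))
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as PLY: {exc}") from exc
        pts = np.asarray(loaded.vertices, dtype=np.float64)
        labels = None
        raw = loaded.metadata.get("_ply_raw", {}).get("vertex", {})
        data = raw.get("data")
        if data is not None:
            if isinstance(data, dict) and "label" in data:
                labels = np.asarray(data["label"]).ravel().astype(np.int64)
            elif getattr(data, "dtype", None) is not None and data.dtype.names and "label" in data.dtype.names:
                labels = np.asarray(data["label"]).ravel().astype(np.int64)
        if labels is None and not allow_unlabeled:
            raise FormatError(
                f"{path} has no per-vertex 'label' property "
                "(pass allow_unlabeled=True to read it as an unlabeled cloud)"
            )
        return LabeledCloud(pts, labels=labels, class_count=class_count)
    arr = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if arr.shape[1] == 4:
        return LabeledCloud(
            arr[:, :3], labels=arr[:, 3].astype(np.int64), class_count=class_count
        )
    if arr.shape[1] == 3:
        if not allow_unlabeled:
            raise FormatError(f"{path} has 3 columns but labels were required")
        return LabeledCloud(arr, labels=None, class_count=class_count)
    raise FormatError(f"{path}: expected 3 or 4 columns, found {arr.shape[1]}")
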