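"""Synthetic labeled dental-arch point clouds.

Clinical intraoral scans are not publicly distributable, so this module
generates geometrically labeled stand-ins: two parabolic arches (upper arch
mirrored above the lower) carrying up to eight superellipsoid teeth per
quadrant on a vaulted gingiva ridge.  Tooth crown dimensions follow typical
permanent-dentition crown widths (mm) and the superellipsoid exponent varies
by tooth type, so molars are boxy and incisors tapered — a deliberate
shape contrast, not anatomical realism.

Five scenario modifiers emulate common orthodontic presentations:

* ``normal`` — regular spacing;
* ``crowded`` — inter-tooth gaps shrunk 30–50% with lateral/rotational jitter
  and near-contact allowed;
* ``missing`` — one random tooth removed, gingiva continuous underneath;
* ``malformed`` — one random tooth anisotropically rescaled by U[0.4, 1.6];
* ``partial_eruption`` — one random quadrant's last molar erupted only a
  U[0.2, 0.6] fraction (crown clipped at the gingival crest).

Every cloud is exactly reproducible from its spec (including seed).
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_formats import LabeledCloud, LabelScheme

__all__ = ["ArchSpec", "SCENARIOS", "generate_arch", "generate_dataset", "write_manifest"]

SCENARIOS = ("normal", "crowded", "missing", "malformed", "partial_eruption")

#: crown size (mesiodistal width, buccolingual depth, height, all mm) and
#: superellipsoid exponent per tooth position T1..T8
_TOOTH_DIMS: dict[int, tuple[float, float, float, float]] = {
    1: (8.5, 7.0, 10.0, 1.4),
    2: (6.6, 6.5, 9.0, 1.4),
    3: (7.6, 8.0, 10.5, 1.2),
    4: (7.0, 9.0, 8.5, 0.9),
    5: (6.8, 9.0, 8.0, 0.9),
    6: (10.5, 11.0, 7.5, 0.7),
    7: (10.0, 10.5, 7.0, 0.7),
    8: (9.0, 10.0, 6.5, 0.75),
}


@dataclass(frozen=True)
class ArchSpec:
    """Full-dentition generator parameters (both jaws by default)."""

    teeth_per_quadrant: int = 8
    points_per_cloud: int = 8192
    noise_sd: float = 0.05  # mm, isotropic Gaussian scanner noise
    scenario: str = "normal"
    seed: int = 0
    jaws: tuple[str, ...] = ("lower", "upper")
    arch_half_width: float = 27.0  # mm, base parabola half-width
    arch_depth: float = 36.0  # mm, base parabola depth
    gum_half_width: float = 7.0  # mm, gingiva ridge half-width
    gum_height: float = 4.0  # mm, gingiva crest height
    tooth_gap: float = 1.0  # mm, nominal inter-tooth gap along the arch
    jaw_separation: float = 8.0  # mm between opposing crown tips

    def __post_init__(self) -> None:
        if not 1 <= self.teeth_per_quadrant <= 8:
            raise ValueError("teeth_per_quadrant must be in [1, 8]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.points_per_cloud < 64:
            raise ValueError("points_per_cloud too small")

    def digest(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.md5(payload).hexdigest()[:10]


# --------------------------------------------------------------------------
# geometry helpers


def _superellipsoid_surface(
    rng: np.random.Generator, n: int, axes: np.ndarray, eps: float
) -> np.ndarray:
    """Direction-uniform samples of the Lp surface |x/a|^p+|y/b|^p+|z/c|^p=1.

    With a single exponent the implicit form is radially solvable in closed
    form: for direction u, the surface point is u·f(u)^(-eps/2).
    """
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    f = _superellipsoid_implicit(u, axes, eps)
    return u * f[:, None] ** (-eps / 2.0)


def _superellipsoid_implicit(pts: np.ndarray, axes: np.ndarray, eps: float) -> np.ndarray:
    """Inside-outside value f: f=1 on the surface, <1 inside, >1 outside."""
    p = 2.0 / eps
    return np.sum(np.abs(pts / axes) ** p, axis=-1)


class _ArchCurve:
    """Arc-length parameterized parabola y = depth·(1 - (x/hw)^2)."""

    def __init__(self, half_width: float, depth: float):
        t = np.linspace(-1.0, 1.0, 4001)
        x = half_width * t
        y = depth * (1.0 - t**2)
        seg = np.hypot(np.diff(x), np.diff(y))
        s = np.concatenate([[0.0], np.cumsum(seg)])
        self._x, self._y, self._s = x, y, s
        self.length = float(s[-1])

    def scaled(self, target_length: float) -> "_ArchCurve":
        sigma = target_length / self.length
        out = object.__new__(_ArchCurve)
        out._x, out._y, out._s = self._x * sigma, self._y * sigma, self._s * sigma
        out.length = self.length * sigma
        return out

    def position(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        return np.stack(
            [np.interp(s, self._s, self._x), np.interp(s, self._s, self._y)], axis=-1
        )

    def tangent(self, s: np.ndarray) -> np.ndarray:
        h = self.length * 1e-4
        d = self.position(np.asarray(s) + h) - self.position(np.asarray(s) - h)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)


@dataclass
class _Tooth:
    cls: int  # internal class index 1..32
    center: np.ndarray  # (3,)
    axes: np.ndarray  # semi-axes (3,)
    eps: float
    angle: float  # rotation about z
    eruption: float  # fraction of crown height above the crest

    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def implicit(self, world_pts: np.ndarray) -> np.ndarray:
        local = (world_pts - self.center) @ self.rotation()
        return _superellipsoid_implicit(local, self.axes, self.eps)


# --------------------------------------------------------------------------
# arch assembly


def _quadrant_classes(jaw: str, teeth_per_quadrant: int) -> list[int]:
    """Class indices in order along the arch (distal right → distal left)."""
    scheme = LabelScheme()
    if jaw == "upper":
        q_right, q_left = 1, 2
    else:
        q_right, q_left = 4, 3
    right = [scheme.class_of_fdi(10 * q_right + p)
             for p in range(teeth_per_quadrant, 0, -1)]
    left = [scheme.class_of_fdi(10 * q_left + p)
            for p in range(1, teeth_per_quadrant + 1)]
    return right + left


def _build_teeth(
    spec: ArchSpec, jaw: str, rng: np.random.Generator
) -> tuple[list[_Tooth], _ArchCurve]:
    classes = _quadrant_classes(jaw, spec.teeth_per_quadrant)
    scheme = LabelScheme()
    dims = [np.array(_TOOTH_DIMS[scheme.type_index(c)][:3]) for c in classes]
    eps_list = [_TOOTH_DIMS[scheme.type_index(c)][3] for c in classes]

    # scenario draws (fixed order keeps everything reproducible)
    gap = spec.tooth_gap
    if spec.scenario == "crowded":
        gap = spec.tooth_gap * rng.uniform(0.5, 0.7)
        lateral_sd, angle_sd = 0.9, np.deg2rad(12.0)
        contact_factor = 0.55
    else:
        lateral_sd, angle_sd = 0.25, np.deg2rad(4.0)
        contact_factor = 0.8
    size_scale = [np.ones(3) for _ in classes]
    if spec.scenario == "malformed":
        idx = int(rng.integers(len(classes)))
        size_scale[idx] = rng.uniform(0.4, 1.6, size=3)
    # normally erupted crowns show ~85% of their height above the crest; the
    # embedded base (and its underside cap) is hidden by gingiva, giving a
    # clean emergence boundary like a real gingival margin
    eruption = {c: 0.85 for c in classes}
    if spec.scenario == "partial_eruption" and spec.teeth_per_quadrant == 8:
        last_molars = [classes[0], classes[-1]]  # distal ends of this arch
        eruption[last_molars[int(rng.integers(2))]] = float(rng.uniform(0.2, 0.6))

    widths = [float(d[0] * s[0]) for d, s in zip(dims, size_scale)]
    total = sum(widths) + gap * (len(widths) + 1)
    base = _ArchCurve(
        spec.arch_half_width * (1.03 if jaw == "upper" else 1.0), spec.arch_depth
    )
    curve = base.scaled(total)

    for attempt in range(6):
        jrng = np.random.default_rng(rng.integers(2**31))
        s = gap
        teeth: list[_Tooth] = []
        for cls, d, sc, w in zip(classes, dims, size_scale, widths):
            center_s = s + w / 2.0
            s += w + gap
            pos2 = curve.position(np.array([center_s]))[0]
            tan2 = curve.tangent(np.array([center_s]))[0]
            normal2 = np.array([-tan2[1], tan2[0]])
            lateral = jrng.normal(0.0, lateral_sd)
            axes = d * sc / 2.0
            e = eruption[cls]
            zc = spec.gum_height + (e - 0.5) * d[2] * sc[2]
            center = np.array(
                [pos2[0] + lateral * normal2[0], pos2[1] + lateral * normal2[1], zc]
            )
            angle = np.arctan2(tan2[1], tan2[0]) + jrng.normal(0.0, angle_sd)
            teeth.append(_Tooth(cls, center, axes, eps_list[classes.index(cls)], angle, e))
        # near-contact guard: neighbors may touch but not interpenetrate deeply
        ok = True
        for a, b in zip(teeth[:-1], teeth[1:]):
            min_d = contact_factor * (a.axes[0] + b.axes[0])
            if np.linalg.norm(a.center[:2] - b.center[:2]) < min_d:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not place teeth without deep overlap after retries "
            f"(scenario={spec.scenario}, jaw={jaw}, seed={spec.seed})"
        )

    if spec.scenario == "missing":
        teeth.pop(int(rng.integers(len(teeth))))
    return teeth, curve


def _sample_tooth(tooth: _Tooth, n: int, crest: float, rng: np.random.Generator) -> np.ndarray:
    """Surface points of one tooth, clipped below the gingival crest plane."""
    rot = tooth.rotation()
    collected: list[np.ndarray] = []
    have = 0
    for _ in range(40):
        local = _superellipsoid_surface(rng, max(2 * n, 256), tooth.axes, tooth.eps)
        world = local @ rot.T + tooth.center
        keep = world[:, 2] >= crest
        pts = world[keep]
        collected.append(pts)
        have += len(pts)
        if have >= n:
            break
    out = np.concatenate(collected, axis=0)
    if len(out) < n:  # pragma: no cover - extreme eruption fractions only
        raise RuntimeError("tooth surface almost fully submerged; cannot sample")
    return out[:n]


def _sample_gum(
    curve: _ArchCurve, spec: ArchSpec, teeth: list[_Tooth], n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vaulted gingiva ridge along the arch, avoiding tooth interiors."""
    pts_out: list[np.ndarray] = []
    have = 0
    for _ in range(40):
        m = max(2 * n, 512)
        s = rng.uniform(0.0, curve.length, m)
        v = rng.uniform(-spec.gum_half_width, spec.gum_half_width, m)
        z = spec.gum_height * np.sqrt(
            np.maximum(0.0, 1.0 - (v / spec.gum_half_width) ** 2)
        )
        pos = curve.position(s)
        tan = curve.tangent(s)
        normal = np.stack([-tan[:, 1], tan[:, 0]], axis=1)
        world = np.column_stack([pos + normal * v[:, None], z])
        inside = np.zeros(m, dtype=bool)
        for tooth in teeth:
            near = (
                np.linalg.norm(world[:, :2] - tooth.center[:2], axis=1)
                < tooth.axes[:2].max() + 1.0
            )
            if near.any():
                inside[near] |= tooth.implicit(world[near]) < 1.0
        keep = world[~inside]
        pts_out.append(keep)
        have += len(keep)
        if have >= n:
            break
    out = np.concatenate(pts_out, axis=0)
    if len(out) < n:  # pragma: no cover
        raise RuntimeError("gingiva sampling failed to reach the point budget")
    return out[:n]


def _tooth_area_proxy(t: _Tooth) -> float:
    a, b, c = t.axes
    return float(a * b + a * c + b * c) * max(t.eruption, 0.2)


def generate_arch(spec: ArchSpec) -> LabeledCloud:
    """One full labeled cloud per the spec; deterministic for a fixed spec."""
    return generate_arch_parts(spec)[0]


def generate_arch_parts(spec: ArchSpec) -> tuple[LabeledCloud, list[_Tooth]]:
    """As :func:`generate_arch`, also returning the tooth primitives in the
    final cloud coordinate frame (useful for geometric validation)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7007]))
    jaw_data: list[tuple[np.ndarray, np.ndarray]] = []
    all_teeth: list[_Tooth] = []
    jaw_budget = np.full(len(spec.jaws), spec.points_per_cloud // len(spec.jaws))
    jaw_budget[0] += spec.points_per_cloud - jaw_budget.sum()
    # single-tooth scenarios affect exactly one jaw; crowding affects both
    affected_jaw = int(rng.integers(len(spec.jaws)))
    for j, (jaw, budget) in enumerate(zip(spec.jaws, jaw_budget)):
        jaw_scenario = spec.scenario
        if spec.scenario in ("missing", "malformed", "partial_eruption") and j != affected_jaw:
            jaw_scenario = "normal"
        jaw_spec = spec if jaw_scenario == spec.scenario else ArchSpec(
            **{**asdict(spec), "scenario": jaw_scenario, "jaws": tuple(spec.jaws)}
        )
        teeth, curve = _build_teeth(jaw_spec, jaw, rng)
        gum_n = int(round(0.35 * budget))
        tooth_n = budget - gum_n
        areas = np.array([_tooth_area_proxy(t) for t in teeth])
        alloc = np.maximum(1, np.round(tooth_n * areas / areas.sum()).astype(int))
        while alloc.sum() > tooth_n:
            alloc[int(np.argmax(alloc))] -= 1
        while alloc.sum() < tooth_n:
            alloc[int(np.argmin(alloc))] += 1
        pts_list, lab_list = [], []
        for tooth, cnt in zip(teeth, alloc):
            p = _sample_tooth(tooth, int(cnt), spec.gum_height, rng)
            pts_list.append(p)
            lab_list.append(np.full(len(p), tooth.cls, dtype=np.int64))
        gum = _sample_gum(curve, spec, teeth, gum_n, rng)
        pts_list.append(gum)
        lab_list.append(np.zeros(len(gum), dtype=np.int64))
        pts = np.concatenate(pts_list)
        labs = np.concatenate(lab_list)
        # center the arch laterally/front-back before stacking jaws
        shift_xy = pts[:, :2].mean(axis=0)
        pts[:, :2] -= shift_xy
        for tooth in teeth:
            tooth.center = tooth.center - np.array([*shift_xy, 0.0])
        if jaw == "upper":
            # occlusal surfaces face downward in the aligned frame; mirroring
            # z maps each superellipsoid onto itself with a mirrored center
            crown_reach = spec.gum_height + max(h for *_, h, _ in _TOOTH_DIMS.values())
            z_off = 2 * crown_reach + spec.jaw_separation
            pts[:, 2] = z_off - pts[:, 2]
            for tooth in teeth:
                tooth.center = tooth.center * np.array([1.0, 1.0, -1.0]) + np.array(
                    [0.0, 0.0, z_off]
                )
        jaw_data.append((pts, labs))
        all_teeth.extend(teeth)
    points = np.concatenate([p for p, _ in jaw_data])
    labels = np.concatenate([l for _, l in jaw_data])
    if spec.noise_sd > 0:
        points = points + rng.normal(0.0, spec.noise_sd, size=points.shape)
    return LabeledCloud(points, labels=labels, class_count=33), all_teeth


# --------------------------------------------------------------------------
# dataset generation


def generate_dataset(
    n_clouds: int,
    scenario_mix: dict[str, float] | None = None,
    seed: int = 0,
    points_per_cloud: int = 8192,
    noise_sd: float = 0.05,
    teeth_per_quadrant: int = 8,
) -> tuple[list[LabeledCloud], list[dict]]:
    """Draw ``n_clouds`` specs from the scenario mix and generate them all.

    Returns the clouds plus a manifest row per cloud (id, scenario, spec
    digest, class inventory).  The default mix is uniform over the five
    scenarios.
    """
    if scenario_mix is None:
        scenario_mix = {s: 1.0 / len(SCENARIOS) for s in SCENARIOS}
    names = list(scenario_mix)
    probs = np.array([scenario_mix[s] for s in names], dtype=np.float64)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("scenario mix proportions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDA7A]))
    clouds: list[LabeledCloud] = []
    manifest: list[dict] = []
    for i in range(n_clouds):
        scenario = names[int(rng.choice(len(names), p=probs))]
        spec = ArchSpec(
            teeth_per_quadrant=teeth_per_quadrant,
            points_per_cloud=points_per_cloud,
            noise_sd=noise_sd,
            scenario=scenario,
            seed=int(rng.integers(2**31)),
        )
        cloud = generate_arch(spec)
        clouds.append(cloud)
        manifest.append(
            {
                "cloud_id": i,
                "scenario": scenario,
                "seed": spec.seed,
                "spec_digest": spec.digest(),
                "n_points": len(cloud),
                "classes_present": " ".join(map(str, np.unique(cloud.labels))),
            }
        )
    return clouds, manifest


def write_manifest(manifest: list[dict], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()))
        writer.writeheader()
        writer.writerows(manifest)
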