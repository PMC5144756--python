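"""Seeded generators of synthetic tractography for testing the pipeline.

The generators build brain-scale scenes in world RAS mm: bundles of smooth
streamlines around parametric centerlines (straight segments, vertical arcs
emulating corticospinal-tract geometry, and C-shaped arcs emulating the
arcuate fasciculus), mirrored about the midsagittal plane x = 0 when
bilateral, with optional planted outlier fibers, per-subject affine jitter,
smooth nonlinear warps, simulated tumors, and spherical activation masks.
Every generator is a pure function of its spec plus seed, and ground-truth
labels/transforms are always returned so clustering and registration accuracy
can be scored without stored fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .fiber_geometry import reflect_points
from .tract_io import Fiber, LinearTransform, Tractogram

__all__ = [
    "BundleSpec",
    "CohortSpec",
    "make_bundle",
    "make_subject",
    "make_cohort",
    "simulate_tumor",
    "make_activation_mask",
    "default_bundle_specs",
]


@dataclass
class BundleSpec:
    """One synthetic bundle: a centerline plus radial Gaussian dispersion.

    kind : {"straight", "arc", "c_shape"}
        Centerline family.  "arc" sweeps ~120 degrees (CST-like vertical
        arch), "c_shape" sweeps ~220 degrees (AF-like hook).
    length_mm : float
        Target centerline arc length.
    center : (3,) world position of the centerline midpoint, mm.
    axis_rotation_deg : rotation of the curve plane about z, degrees.
    n_fibers : fibers drawn around the centerline.
    dispersion : mm, scale of the smooth random offsets.
    """

    kind: str = "straight"
    length_mm: float = 90.0
    center: tuple = (0.0, 0.0, 0.0)
    axis_rotation_deg: float = 0.0
    n_fibers: int = 40
    dispersion: float = 2.5
    n_points: int = 30

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "arc", "c_shape"):
            raise ValueError(f"unknown centerline kind {self.kind!r}")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")


def _centerline(spec: BundleSpec) -> np.ndarray:
    """Centerline points (n_points, 3) before placement."""
    n = spec.n_points
    L = spec.length_mm
    t = np.linspace(0.0, 1.0, n)
    if spec.kind == "straight":
        pts = np.stack([np.zeros(n), (t - 0.5) * L, np.zeros(n)], axis=1)
    else:
        span = np.deg2rad(120.0 if spec.kind == "arc" else 220.0)
        radius = L / span
        theta = (t - 0.5) * span
        # curve in the y-z plane, apex up
        pts = np.stack([np.zeros(n),
                        radius * np.sin(theta),
                        radius * np.cos(theta) - radius], axis=1)
    ang = np.deg2rad(spec.axis_rotation_deg)
    rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                    [np.sin(ang), np.cos(ang), 0.0],
                    [0.0, 0.0, 1.0]])
    pts = pts @ rot.T
    pts = pts - pts.mean(axis=0) + np.asarray(spec.center, dtype=float)
    return pts


def _smooth_offsets(rng: np.random.Generator, n_points: int,
                    scale: float, n_ctrl: int = 4) -> np.ndarray:
    """Smooth random (n_points, 3) offset curve of the given scale."""
    if scale == 0:
        return np.zeros((n_points, 3))
    tc = np.linspace(0.0, 1.0, n_ctrl)
    ctrl = rng.normal(scale=scale, size=(n_ctrl, 3))
    return CubicSpline(tc, ctrl, axis=0)(np.linspace(0.0, 1.0, n_points))


def make_bundle(spec: BundleSpec, seed: int = 0,
                label: int = 0) -> tuple[Tractogram, np.ndarray]:
    """Generate one bundle and its ground-truth labels (all ``label``)."""
    rng = np.random.default_rng(seed)
    center = _centerline(spec)
    fibers = []
    for _ in range(spec.n_fibers):
        pts = center + _smooth_offsets(rng, spec.n_points, spec.dispersion)
        fibers.append(Fiber(pts))
    labels = np.full(spec.n_fibers, label, dtype=np.int64)
    return Tractogram(subject_id="bundle", fibers=fibers), labels


def _random_outlier(rng: np.random.Generator, bounds: np.ndarray,
                    n_points: int = 30) -> np.ndarray:
    """A plausible-but-wrong smooth polyline spanning the scene box."""
    lo, hi = bounds
    ctrl = rng.uniform(lo, hi, size=(4, 3))
    t = np.linspace(0.0, 1.0, n_points)
    return CubicSpline(np.linspace(0, 1, 4), ctrl, axis=0)(t)


def make_subject(specs: Sequence[BundleSpec], bilateral: bool = True,
                 outlier_fraction: float = 0.0, seed: int = 0,
                 subject_id: str = "subject",
                 ) -> tuple[Tractogram, np.ndarray]:
    """Assemble a subject from bundles; outliers carry label -1.

    With ``bilateral=True`` each bundle is duplicated by mirroring about
    x = 0; the mirror shares the original's label, as bilateral clustering
    treats hemispheric twins as one structure.
    """
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    fibers: list[Fiber] = []
    labels: list[int] = []
    for b, spec in enumerate(specs):
        tr, lb = make_bundle(spec, seed=int(rng.integers(2 ** 31)), label=b)
        fibers.extend(tr.fibers)
        labels.extend(lb.tolist())
        if bilateral:
            tr2, _ = make_bundle(spec, seed=int(rng.integers(2 ** 31)), label=b)
            fibers.extend(Fiber(reflect_points(f.points)) for f in tr2.fibers)
            labels.extend([b] * len(tr2))
    pts = np.concatenate([f.points for f in fibers])
    bounds = np.stack([pts.min(axis=0), pts.max(axis=0)])
    n_real = len(fibers)
    n_out = int(round(outlier_fraction * n_real / (1.0 - outlier_fraction)))
    for _ in range(n_out):
        fibers.append(Fiber(_random_outlier(rng, bounds)))
        labels.append(-1)
    return (Tractogram(subject_id=subject_id, fibers=fibers, frame="atlas"),
            np.asarray(labels, dtype=np.int64))


@dataclass
class CohortSpec:
    """A multi-subject cohort: shared anatomy plus per-subject jitter.

    Translation/rotation/scale jitter ranges bound the random affine applied
    to each subject; the drawn affines are centered so their group average is
    the identity (a registration can only recover transforms up to the group
    mean, so the planted ground truth is made mean-free by construction).
    """

    n_subjects: int = 5
    bundles: Sequence[BundleSpec] = field(default_factory=lambda: default_bundle_specs())
    bilateral: bool = True
    outlier_fraction: float = 0.0
    translation_mm: float = 0.0
    rotation_deg: float = 0.0
    scale_range: tuple = (1.0, 1.0)
    warp_amplitude_mm: float = 0.0
    seed: int = 0


def default_bundle_specs(n_fibers: int = 40,
                         dispersion: float = 2.5) -> list[BundleSpec]:
    """Six well-separated brain-scale bundles (one hemisphere; mirror for
    bilateral scenes).  Geometry loosely follows major association and
    projection tracts: a CST-like vertical arc, an AF-like C-shape, long
    straight fronto-occipital and temporo-occipital runs, a hook-shaped
    uncinate-like bundle and a cingulum-like arc."""
    return [
        BundleSpec("arc", 100.0, (25.0, -12.0, 22.0), 0.0, n_fibers, dispersion),
        BundleSpec("c_shape", 110.0, (50.0, -30.0, 2.0), 0.0, n_fibers, dispersion),
        BundleSpec("straight", 120.0, (33.0, 5.0, -12.0), 10.0, n_fibers, dispersion),
        BundleSpec("straight", 95.0, (48.0, -35.0, -25.0), -20.0, n_fibers, dispersion),
        BundleSpec("c_shape", 80.0, (25.0, 35.0, -18.0), 90.0, n_fibers, dispersion),
        BundleSpec("arc", 90.0, (12.0, 0.0, 42.0), 0.0, n_fibers, dispersion),
    ]


def _random_affine(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    t = rng.uniform(-spec.translation_mm, spec.translation_mm, size=3)
    angles = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg,
                                    size=3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    s = rng.uniform(*spec.scale_range)
    m = np.eye(4)
    m[:3, :3] = (rz @ ry @ rx) * s
    m[:3, 3] = t
    return m


def make_cohort(spec: CohortSpec) -> tuple[list[Tractogram],
                                           list[np.ndarray],
                                           list[LinearTransform]]:
    """Generate subjects, ground-truth labels, and the planted transforms.

    Returns (tractograms, labels, true_transforms); each tractogram is the
    shared scene mapped through its subject's (mean-removed) affine, plus an
    optional smooth sinusoidal warp of the configured amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    mats = [_random_affine(rng, spec) for _ in range(spec.n_subjects)]
    mean = np.mean(mats, axis=0)
    mean_inv = np.linalg.inv(mean)
    mats = [m @ mean_inv for m in mats]
    subjects, all_labels, transforms = [], [], []
    for i, mat in enumerate(mats):
        tract, labels = make_subject(
            spec.bundles, bilateral=spec.bilateral,
            outlier_fraction=spec.outlier_fraction,
            seed=int(rng.integers(2 ** 31)), subject_id=f"synth{i:02d}")
        tf = LinearTransform(mat)
        fibers = []
        for f in tract.fibers:
            pts = tf.apply(f.points)
            if spec.warp_amplitude_mm > 0:
                pts = pts + _sin_warp(pts, spec.warp_amplitude_mm)
            fibers.append(Fiber(pts))
        subjects.append(Tractogram(subject_id=tract.subject_id,
                                   fibers=fibers, frame="subject"))
        all_labels.append(labels)
        transforms.append(tf)
    return subjects, all_labels, transforms


def _sin_warp(pts: np.ndarray, amplitude: float,
              wavelength: float = 120.0) -> np.ndarray:
    disp = np.zeros_like(pts)
    disp[:, 0] = amplitude * np.sin(2 * np.pi * pts[:, 1] / wavelength)
    disp[:, 2] = amplitude * np.cos(2 * np.pi * pts[:, 1] / wavelength)
    return disp


def simulate_tumor(subject: Tractogram, center, radius: float,
                   displacement_scale: float = 0.0,
                   ) -> tuple[Tractogram, dict]:
    """Delete fibers entering a spherical tumor; push the rest outward.

    Fibers with any point within ``radius`` of ``center`` are removed
    (disruption); every point of each surviving fiber is displaced radially
    away from the center by displacement_scale * exp(-(r/radius)^2)
    (mass effect).  Returns the lesioned tractogram and a report with the
    removed and displaced original fiber indices.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = np.asarray(center, dtype=float)
    kept_fibers, removed, displaced = [], [], []
    for i, f in enumerate(subject.fibers):
        r = np.linalg.norm(f.points - c, axis=1)
        if np.any(r < radius):
            removed.append(i)
            continue
        if displacement_scale > 0:
            push = displacement_scale * np.exp(-((r / radius) ** 2))
            direction = (f.points - c) / r[:, None]
            kept_fibers.append(Fiber(f.points + direction * push[:, None]))
            displaced.append(i)
        else:
            kept_fibers.append(f)
    out = Tractogram(subject_id=subject.subject_id, fibers=kept_fibers,
                     frame=subject.frame)
    return out, {"removed": removed, "displaced": displaced}


def make_activation_mask(center, radius: float, grid_shape=(32, 32, 32),
                         voxel_size=1.0, origin=None):
    """Spherical binary activation mask on a regular grid.

    A voxel is foreground iff its center lies within ``radius`` of
    ``center``.  By default the grid is placed so the sphere sits at its
    middle; pass ``origin`` (world position of voxel (0,0,0)) to override.
    """
    from .tract_io import VolumeMask

    center = np.asarray(center, dtype=float)
    shape = np.asarray(grid_shape, dtype=int)
    vox = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    if origin is None:
        origin = center - vox * (shape - 1) / 2.0
    origin = np.asarray(origin, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vox)
    affine[:3, 3] = origin
    lo_ok = np.all(center - radius >= origin - vox / 2)
    hi_ok = np.all(center + radius <= origin + vox * (shape - 0.5))
    if not (lo_ok and hi_ok):
        raise ValueError("sphere does not fit inside the mask grid")
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * vox + origin
    inside = np.linalg.norm(centers - center, axis=1) <= radius
    data = inside.reshape(tuple(shape)).astype(np.uint8)
    return VolumeMask(data=data, voxel_to_world=affine)
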