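"""Synthetic training data: posed, noise-corrupted 2D renders of a model.

The noise pipeline mirrors the physical corruption of a labelled sample:
per-point dropout (missing fluorophores), multiple binding (each surviving
point spawns one or more fluorophores), and scatter (an isotropic 3D
Gaussian displacement of every emitted fluorophore).  Noise acts on the 3D
points; the pose, orthographic projection and Gaussian splat follow.

Datasets are generated lazily: each base sample stores its corrupted 3D
fluorophores and pose, and every augmented copy applies a uniform-random
z-rotation on top, so any sample can be re-rendered at any input-sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (
    PointCloud3D,
    Pose,
    axis_angle_to_matrix,
    matrix_to_axis_angle,
    sample_uniform_rotation,
    transform_project,
)
from .renderer import RenderConfig, RenderedImage, splat

__all__ = [
    "DegenerateSampleError",
    "NoiseConfig",
    "SimulatedSample",
    "SyntheticDataset",
    "apply_missing",
    "apply_scatter",
    "apply_spawn",
    "make_dataset",
    "make_parametric_model",
]

logger = logging.getLogger(__name__)


class DegenerateSampleError(ValueError):
    """Raised when noise removes every fluorophore from a sample."""


@dataclass(frozen=True)
class NoiseConfig:
    """Parameters of the three experimental-noise models.

    ``scatter_sigma`` is expressed in pixels and converted to world units
    through the frame's pixel pitch when applied.
    """

    scatter_sigma: float = 0.0
    p_missing: float = 0.0
    spawn_rate: float = 0.0
    max_spawn: int = 1

    def __post_init__(self) -> None:
        if self.scatter_sigma < 0:
            raise ValueError("scatter_sigma must be >= 0")
        if not 0.0 <= self.p_missing <= 1.0:
            raise ValueError("p_missing must be a probability")
        if not 0.0 <= self.spawn_rate <= 1.0:
            raise ValueError("spawn_rate must be a probability")
        if self.max_spawn < 1:
            raise ValueError("max_spawn must be >= 1")

    @property
    def enabled(self) -> bool:
        return (
            self.scatter_sigma > 0
            or self.p_missing > 0
            or (self.spawn_rate > 0 and self.max_spawn > 1)
        )


@dataclass
class SimulatedSample:
    """One training image with its generating pose and 2D fluorophores."""

    image: RenderedImage
    true_pose: Pose
    fluorophores: np.ndarray  # (M, 2) world coordinates after projection


def apply_scatter(
    points: np.ndarray,
    scatter_sigma: float,
    rng: np.random.Generator,
    pixels_per_world: float = 64.0,
) -> np.ndarray:
    """Displace every point by an independent isotropic 3D Gaussian.

    ``scatter_sigma`` is a per-axis standard deviation in pixels; it is
    divided by ``pixels_per_world`` to act in world units.
    """
    if scatter_sigma < 0:
        raise ValueError("scatter_sigma must be >= 0")
    points = np.asarray(points, dtype=np.float64)
    if scatter_sigma == 0:
        return points.copy()
    sd = scatter_sigma / pixels_per_world
    return points + rng.normal(scale=sd, size=points.shape)


def apply_missing(
    points: np.ndarray, p_missing: float, rng: np.random.Generator
) -> np.ndarray:
    """Independently drop each point with probability ``p_missing``."""
    if not 0.0 <= p_missing <= 1.0:
        raise ValueError("p_missing must be a probability")
    points = np.asarray(points, dtype=np.float64)
    keep = rng.random(points.shape[0]) >= p_missing
    if not keep.any():
        raise DegenerateSampleError("all points dropped")
    return points[keep]


def apply_spawn(
    points: np.ndarray,
    spawn_rate: float,
    max_spawn: int,
    scatter_sigma: float,
    rng: np.random.Generator,
    pixels_per_world: float = 64.0,
) -> np.ndarray:
    """Emit ``1 + Binomial(max_spawn - 1, spawn_rate)`` fluorophores per
    point, each independently scattered.

    The additive-one form guarantees at least one fluorophore per labelled
    point, so missing-ness stays controlled solely by the dropout model.
    """
    if max_spawn < 1:
        raise ValueError("max_spawn must be >= 1")
    if not 0.0 <= spawn_rate <= 1.0:
        raise ValueError("spawn_rate must be a probability")
    points = np.asarray(points, dtype=np.float64)
    k = 1 + rng.binomial(max_spawn - 1, spawn_rate, size=points.shape[0])
    emitted = np.repeat(points, k, axis=0)
    return apply_scatter(emitted, scatter_sigma, rng, pixels_per_world)


def corrupt_points(
    points: np.ndarray,
    noise: NoiseConfig,
    rng: np.random.Generator,
    pixels_per_world: float = 64.0,
) -> np.ndarray:
    """Full noise pipeline on 3D points: missing, then spawn (which
    scatters every emitted fluorophore)."""
    pts = np.asarray(points, dtype=np.float64)
    if noise.p_missing > 0:
        pts = apply_missing(pts, noise.p_missing, rng)
    return apply_spawn(
        pts, noise.spawn_rate, noise.max_spawn, noise.scatter_sigma, rng, pixels_per_world
    )


class SyntheticDataset:
    """Lazily rendered synthetic dataset.

    ``n_base`` independently posed, independently corrupted copies of the
    model, each augmented ``augment_factor`` times by a uniform-random
    rotation about the viewing (z) axis applied before rendering.  Sample
    ``i`` corresponds to base ``i // augment_factor``.
    """

    def __init__(
        self,
        model: PointCloud3D,
        base_fluorophores: list[np.ndarray],
        base_poses: list[Pose],
        aug_angles: np.ndarray,
        sigma: float,
        render_config: RenderConfig,
        intensity_scale: float = 1.0,
    ) -> None:
        self.model = model
        self.base_fluorophores = base_fluorophores
        self.base_poses = base_poses
        self.aug_angles = aug_angles
        self.sigma = float(sigma)
        self.render_config = render_config
        self.intensity_scale = float(intensity_scale)
        self.n_base = len(base_fluorophores)
        self.augment_factor = aug_angles.shape[1]

    def __len__(self) -> int:
        return self.n_base * self.augment_factor

    def pose(self, i: int) -> Pose:
        """Effective pose of sample ``i`` (z-augmentation composed in)."""
        b, a = divmod(i, self.augment_factor)
        base = self.base_poses[b]
        phi = self.aug_angles[b, a]
        Rz = axis_angle_to_matrix(np.array([0.0, 0.0, phi]))
        rot = matrix_to_axis_angle(Rz @ axis_angle_to_matrix(base.rot))
        c, s = np.cos(phi), np.sin(phi)
        trans = np.array(
            [c * base.trans[0] - s * base.trans[1], s * base.trans[0] + c * base.trans[1]]
        )
        return Pose(rot, trans)

    def fluorophores2d(self, i: int) -> np.ndarray:
        """Projected 2D fluorophores of sample ``i`` in world units."""
        b, _ = divmod(i, self.augment_factor)
        return transform_project(self.base_fluorophores[b], self.pose(i))

    def render(self, i: int, sigma: float | None = None) -> RenderedImage:
        """Render sample ``i`` at the dataset input-sigma or any other."""
        s = self.sigma if sigma is None else float(sigma)
        img = splat(self.fluorophores2d(i), s, self.render_config)
        if self.intensity_scale != 1.0:
            img.pixels = img.pixels * self.intensity_scale
        return img

    def sample(self, i: int, sigma: float | None = None) -> SimulatedSample:
        return SimulatedSample(self.render(i, sigma), self.pose(i), self.fluorophores2d(i))

    def __iter__(self):
        return (self.sample(i) for i in range(len(self)))


def make_dataset(
    model: PointCloud3D,
    n_base: int,
    augment_factor: int,
    noise: NoiseConfig,
    sigma: float,
    rng: np.random.Generator,
    render_config: RenderConfig | None = None,
    translation_range: float = 0.3,
    max_retries: int = 100,
) -> SyntheticDataset:
    """Generate ``n_base * augment_factor`` posed, corrupted samples.

    Poses are Haar-uniform rotations with translations uniform in
    ``[-translation_range, translation_range]``; degenerate (empty) noise
    draws are rejected and redrawn.
    """
    if n_base < 1 or augment_factor < 1:
        raise ValueError("n_base and augment_factor must be >= 1")
    config = render_config or RenderConfig()
    ppw = config.pixels_per_world

    fluors: list[np.ndarray] = []
    poses: list[Pose] = []
    n_rejected = 0
    for _ in range(n_base):
        rot = sample_uniform_rotation(rng)
        trans = rng.uniform(-translation_range, translation_range, size=2)
        for _attempt in range(max_retries):
            try:
                pts = corrupt_points(model.vertices, noise, rng, ppw)
                break
            except DegenerateSampleError:
                n_rejected += 1
        else:
            raise DegenerateSampleError(
                f"noise left no fluorophores after {max_retries} redraws"
            )
        fluors.append(pts)
        poses.append(Pose(rot, trans))
    if n_rejected:
        logger.info("redrew %d degenerate noise samples", n_rejected)

    aug = rng.uniform(0.0, 2.0 * np.pi, size=(n_base, augment_factor))
    return SyntheticDataset(model, fluors, poses, aug, sigma, config)


# ---------------------------------------------------------------------------
# parametric ground-truth models


def make_parametric_model(name: str, **params) -> PointCloud3D:
    """Built-in ground-truth shapes: ``two_cylinder``, ``helix``,
    ``random_blob``.  Deterministic for fixed parameters."""
    makers = {
        "two_cylinder": _two_cylinder,
        "helix": _helix,
        "random_blob": _random_blob,
    }
    if name not in makers:
        raise ValueError(f"unknown parametric model {name!r}; choose from {sorted(makers)}")
    return makers[name](**params)


def _cylinder_surface(radius, height, n_rings, points_per_ring, phase=0.0):
    """Points on a cylinder surface with axis z, centred at the origin."""
    z = np.linspace(-height / 2.0, height / 2.0, n_rings)
    ang = np.linspace(0.0, 2.0 * np.pi, points_per_ring, endpoint=False) + phase
    zz, aa = np.meshgrid(z, ang, indexing="ij")
    return np.stack(
        [radius * np.cos(aa), radius * np.sin(aa), zz], axis=-1
    ).reshape(-1, 3)


def _two_cylinder(
    radius_large: float = 0.55,
    height_large: float = 1.1,
    rings_large: int = 10,
    points_per_ring_large: int = 24,
    radius_small: float = 0.16,
    height_small: float = 0.55,
    rings_small: int = 5,
    points_per_ring_small: int = 10,
    top_offset: float = 0.3,
) -> PointCloud3D:
    """Two perpendicular cylinders: a large toroid-like barrel plus a small
    cylinder protruding radially, offset toward the top of the barrel."""
    large = _cylinder_surface(radius_large, height_large, rings_large, points_per_ring_large)
    small = _cylinder_surface(radius_small, height_small, rings_small, points_per_ring_small)
    # rotate small cylinder axis z -> x and shift it outward and upward
    small = small[:, [2, 1, 0]] * np.array([1.0, 1.0, -1.0])
    small[:, 0] += radius_large + height_small / 2.0
    small[:, 2] += top_offset * height_large
    cloud = np.vstack([large, small])
    return PointCloud3D(cloud, label="two_cylinder")


def _helix(
    n_points: int = 100, turns: float = 3.0, radius: float = 0.7, height: float = 1.6
) -> PointCloud3D:
    t = np.linspace(0.0, 1.0, n_points)
    ang = 2.0 * np.pi * turns * t
    pts = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), height * (t - 0.5)], axis=1
    )
    return PointCloud3D(pts, label="helix")


def _random_blob(n_points: int = 100, seed: int = 0) -> PointCloud3D:
    """Uniform points in the unit ball; seeded, hence deterministic."""
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while pts.shape[0] < n_points:
        cand = rng.uniform(-1.0, 1.0, size=(2 * n_points, 3))
        cand = cand[(cand**2).sum(axis=1) <= 1.0]
        pts = np.vstack([pts, cand])
    return PointCloud3D(pts[:n_points], label="random_blob")
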