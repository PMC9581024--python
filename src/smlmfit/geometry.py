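"""Rotation representations, uniform SO(3) sampling and orthographic projection.

Conventions
-----------
* Rotations are stored as axis-angle 3-vectors ``r`` (radians times unit
  axis).  The canonical range is ``||r|| <= pi``; ties at pi are resolved so
  that the axis is lexicographically positive.
* World coordinates are dimensionless with a nominal extent of ``[-1, 1]``
  per axis; :func:`normalise_cloud` rescales arbitrary models into that cube.
* Projection is orthographic: rotate, drop z, translate in-plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointCloud3D",
    "Pose",
    "axis_angle_to_matrix",
    "axis_angle_jacobian",
    "canonicalise_axis_angle",
    "matrix_to_axis_angle",
    "normalise_cloud",
    "sample_uniform_rotation",
    "transform_project",
]


@dataclass
class PointCloud3D:
    """An ``N x 3`` list of vertices in world units.

    Used both for ground-truth models and for the learned reconstruction
    matrix.
    """

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(
                f"vertices must be an (N, 3) array, got shape {self.vertices.shape}"
            )
        if self.vertices.shape[0] < 1:
            raise ValueError("a point cloud needs at least one vertex")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices must be finite")

    def __len__(self) -> int:
        return self.vertices.shape[0]


@dataclass
class Pose:
    """Rigid placement of a model in an image: axis-angle rotation plus
    in-plane translation ``(Tx, Ty)`` in world units."""

    rot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    trans: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.rot = np.asarray(self.rot, dtype=np.float64).reshape(3)
        self.trans = np.asarray(self.trans, dtype=np.float64).reshape(2)
        if not (np.all(np.isfinite(self.rot)) and np.all(np.isfinite(self.trans))):
            raise ValueError("pose components must be finite")

    def matrix(self) -> np.ndarray:
        return axis_angle_to_matrix(self.rot)


def axis_angle_to_matrix(rot: np.ndarray) -> np.ndarray:
    """Convert an axis-angle vector to a 3x3 rotation matrix (Rodrigues).

    Uses a second-order Taylor expansion of the coefficients near zero angle
    so the map stays smooth and exact to machine precision at the origin.
    """
    rot = np.asarray(rot, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(rot)):
        raise ValueError("axis-angle vector must be finite")
    theta2 = float(rot @ rot)
    theta = np.sqrt(theta2)
    K = _cross_matrix(rot)
    if theta < 1e-8:
        # sin(t)/t ~ 1 - t^2/6, (1-cos t)/t^2 ~ 1/2 - t^2/24
        a = 1.0 - theta2 / 6.0
        b = 0.5 - theta2 / 24.0
    else:
        a = np.sin(theta) / theta
        b = (1.0 - np.cos(theta)) / theta2
    return np.eye(3) + a * K + b * (K @ K)


def matrix_to_axis_angle(M: np.ndarray) -> np.ndarray:
    """Inverse of :func:`axis_angle_to_matrix`; returns the canonical vector."""
    M = np.asarray(M, dtype=np.float64)
    # quaternion extraction is numerically stable near theta = pi
    q = _matrix_to_quaternion(M)
    return _quaternion_to_axis_angle(q)


def canonicalise_axis_angle(rot: np.ndarray) -> np.ndarray:
    """Map an axis-angle vector into the canonical range ``||r|| <= pi``.

    Angles are wrapped modulo 2*pi; a wrapped angle above pi flips the axis.
    At exactly pi the representation is two-fold ambiguous (r and -r encode
    the same rotation); the lexicographically positive axis is returned.
    """
    rot = np.asarray(rot, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(rot)):
        raise ValueError("axis-angle vector must be finite")
    theta = float(np.linalg.norm(rot))
    if theta == 0.0:
        return np.zeros(3)
    axis = rot / theta
    theta = np.fmod(theta, 2.0 * np.pi)
    if theta > np.pi:
        theta = 2.0 * np.pi - theta
        axis = -axis
    if abs(theta - np.pi) < 1e-12:
        axis = _lex_positive(axis)
    return theta * axis


def sample_uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    """Draw a Haar-uniform rotation, returned as a canonical axis-angle vector.

    A 4D standard normal vector normalised to the unit sphere is a uniform
    unit quaternion, which pushes forward to the Haar measure on SO(3).
    """
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return _quaternion_to_axis_angle(q)


def transform_project(points: PointCloud3D | np.ndarray, pose: Pose) -> np.ndarray:
    """Rotate a cloud by ``pose.rot``, drop z, then translate by ``pose.trans``.

    Returns an ``(N, 2)`` array in world units with vertex order preserved.
    """
    verts = points.vertices if isinstance(points, PointCloud3D) else np.asarray(points)
    R = axis_angle_to_matrix(pose.rot)
    return verts @ R[:2, :].T + pose.trans


def normalise_cloud(cloud: PointCloud3D) -> PointCloud3D:
    """Centre a cloud on its centroid and rescale it to fit in ``[-1, 1]^3``.

    The largest absolute coordinate after centring maps to 1; degenerate
    single-point clouds are centred only.
    """
    v = cloud.vertices - cloud.vertices.mean(axis=0)
    extent = float(np.abs(v).max())
    if extent > 0:
        v = v / extent
    return PointCloud3D(v, label=cloud.label)


def axis_angle_jacobian(rot: np.ndarray) -> np.ndarray:
    """Derivative of the rotation matrix w.r.t. the axis-angle components.

    Returns ``J`` of shape ``(3, 3, 3)`` with ``J[k] = dR/d rot[k]``, using
    the closed form  dR/dr_k = (r_k [r]x + [r x (I - R) e_k]x) / ||r||^2 . R
    with the small-angle limit dR/dr_k -> [e_k]x.
    """
    rot = np.asarray(rot, dtype=np.float64).reshape(3)
    theta2 = float(rot @ rot)
    R = axis_angle_to_matrix(rot)
    J = np.empty((3, 3, 3))
    if theta2 < 1e-16:
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            J[k] = _cross_matrix(e)
        return J
    K = _cross_matrix(rot)
    ImR = np.eye(3) - R
    for k in range(3):
        v = np.cross(rot, ImR[:, k])
        J[k] = ((rot[k] * K + _cross_matrix(v)) / theta2) @ R
    return J


# ---------------------------------------------------------------------------
# helpers


def _cross_matrix(v: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def _lex_positive(axis: np.ndarray) -> np.ndarray:
    for c in axis:
        if c > 0:
            return axis
        if c < 0:
            return -axis
    return axis


def _matrix_to_quaternion(M: np.ndarray) -> np.ndarray:
    """Shepperd's method; returns (w, x, y, z) with w >= 0."""
    t = np.trace(M)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (M[2, 1] - M[1, 2]) / s, (M[0, 2] - M[2, 0]) / s, (M[1, 0] - M[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(M)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(1.0 + M[i, i] - M[j, j] - M[k, k], 0.0)) * 2.0
        q = np.empty(4)
        q[0] = (M[k, j] - M[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (M[j, i] + M[i, j]) / s
        q[1 + k] = (M[k, i] + M[i, k]) / s
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def _quaternion_to_axis_angle(q: np.ndarray) -> np.ndarray:
    w, xyz = q[0], np.asarray(q[1:])
    if w < 0:
        w, xyz = -w, -xyz
    n = float(np.linalg.norm(xyz))
    if n < 1e-300:
        return np.zeros(3)
    theta = 2.0 * np.arctan2(n, w)
    return canonicalise_axis_angle(theta * xyz / n)
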