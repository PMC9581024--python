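"""Differentiable rendering of 2D point sets as sums of isotropic Gaussians.

Every fluorophore contributes an unnormalised Gaussian of unit peak
amplitude, so integrated intensity scales with fluorophore count; images are
brought to a common scale afterwards with :func:`normalise_image`.

The Gaussian is truncated at ``truncation_radius * sigma`` and shifted down
by its boundary value so the image is a continuous function of the point
coordinates and sigma.  Gradients are provided analytically
(:func:`splat_with_grad`); no autodiff framework is used.

Coordinate conventions: world x, y in ``[-1, 1]`` map to pixels through
``u = (x + 1) / 2 * W`` (0-based, y down), and the centre of pixel
``(row, col)`` sits at ``(col + 0.5, row + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = [
    "RenderConfig",
    "RenderedImage",
    "normalise_image",
    "normalise_image_vjp",
    "splat",
    "splat_with_grad",
]


@dataclass(frozen=True)
class RenderConfig:
    """Geometry of the rendered frame and the Gaussian truncation window."""

    height: int = 128
    width: int = 128
    truncation_radius: float = 4.0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("frame must be at least 8x8 pixels")
        if self.truncation_radius < 3.0:
            raise ValueError("truncation_radius must be >= 3 sigma")

    @property
    def pixels_per_world(self) -> float:
        """Scale of the world [-1, 1] -> pixel map along x."""
        return self.width / 2.0

    def world_to_pixel(self, points2d: np.ndarray) -> np.ndarray:
        p = np.asarray(points2d, dtype=np.float64)
        out = np.empty_like(p)
        out[..., 0] = (p[..., 0] + 1.0) / 2.0 * self.width
        out[..., 1] = (p[..., 1] + 1.0) / 2.0 * self.height
        return out


@dataclass
class RenderedImage:
    """An ``H x W`` non-negative intensity grid plus the sigma it was
    rendered with (pixels)."""

    pixels: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def splat(points2d: np.ndarray, sigma: float, config: RenderConfig) -> RenderedImage:
    """Render world-coordinate points as a sum of truncated Gaussians.

    Points outside the frame are kept; only their in-frame tails contribute.
    An empty point set yields an all-zero image.
    """
    img, _ = _splat_core(points2d, sigma, config, want_grad=False)
    return RenderedImage(img, float(sigma))


def splat_with_grad(
    points2d: np.ndarray, sigma: float, config: RenderConfig
) -> Tuple[RenderedImage, Callable[[np.ndarray], Tuple[np.ndarray, float]]]:
    """Like :func:`splat` but also returns a vector-Jacobian product.

    The returned callable maps an upstream gradient image ``(H, W)`` to
    ``(grad_points2d, grad_sigma)`` in world units.
    """
    img, vjp = _splat_core(points2d, sigma, config, want_grad=True)
    assert vjp is not None
    return RenderedImage(img, float(sigma)), vjp


def normalise_image(img: RenderedImage, scalar: float) -> RenderedImage:
    """Divide by integrated intensity and multiply by a fixed scalar, so the
    output sums exactly to ``scalar`` regardless of the input scale."""
    total = float(img.pixels.sum())
    if total <= 0:
        raise ValueError("cannot normalise an image with no intensity")
    return RenderedImage(img.pixels * (scalar / total), img.sigma)


def normalise_image_vjp(
    pixels: np.ndarray, scalar: float
) -> Tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Normalisation with its vector-Jacobian product, on raw arrays."""
    total = float(pixels.sum())
    if total <= 0:
        raise ValueError("cannot normalise an image with no intensity")
    c = scalar / total
    out = pixels * c

    def vjp(g: np.ndarray) -> np.ndarray:
        # d out_i / d in_j = c * delta_ij - out_i / total
        return c * g - float((g * out).sum()) / total

    return out, vjp


# ---------------------------------------------------------------------------
# core


def _splat_core(points2d, sigma, config, want_grad):
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    in_dtype = getattr(points2d, "dtype", None)
    work_dtype = np.float32 if in_dtype == np.float32 else np.float64
    pts = np.asarray(points2d, dtype=np.float64)
    if pts.size == 0:
        pts = pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points2d must be (N, 2), got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")

    H, W = config.height, config.width
    sigma = float(sigma)
    radius = config.truncation_radius * sigma
    tail = np.exp(-0.5 * config.truncation_radius**2)

    if pts.shape[0] == 0:
        img = np.zeros((H, W))
        if not want_grad:
            return img, None
        return img, lambda g: (np.zeros((0, 2)), 0.0)

    px = config.world_to_pixel(pts)  # (N, 2) pixel coords
    u, v = px[:, 0], px[:, 1]

    K = int(np.floor(2.0 * radius)) + 2
    if K >= max(H, W):
        rows = np.broadcast_to(np.arange(H)[None, :, None], (len(pts), H, W))
        cols = np.broadcast_to(np.arange(W)[None, None, :], (len(pts), H, W))
        rows = rows.reshape(len(pts), -1)
        cols = cols.reshape(len(pts), -1)
        inframe = np.ones(rows.shape, dtype=bool)
    else:
        off = np.arange(K)
        c0 = np.ceil(u - 0.5 - radius).astype(np.int64)
        r0 = np.ceil(v - 0.5 - radius).astype(np.int64)
        cols1 = c0[:, None] + off  # (N, K)
        rows1 = r0[:, None] + off
        cols = np.repeat(cols1[:, None, :], K, axis=1).reshape(len(pts), -1)
        rows = np.repeat(rows1[:, :, None], K, axis=2).reshape(len(pts), -1)
        inframe = (cols >= 0) & (cols < W) & (rows >= 0) & (rows < H)

    du = ((cols + 0.5) - u[:, None]).astype(work_dtype)
    dv = ((rows + 0.5) - v[:, None]).astype(work_dtype)
    d2 = du * du + dv * dv
    valid = inframe & (d2 <= np.float64(radius * radius).astype(work_dtype))
    f_exp = np.where(valid, np.exp(-0.5 * d2 / work_dtype(sigma * sigma)), work_dtype(0.0))
    contrib = np.where(valid, f_exp - work_dtype(tail), work_dtype(0.0))

    flat = (rows * W + cols)[valid]
    img = np.bincount(flat, weights=contrib[valid], minlength=H * W).reshape(H, W)

    if not want_grad:
        return img, None

    sx, sy = W / 2.0, H / 2.0

    def vjp(g: np.ndarray) -> Tuple[np.ndarray, float]:
        g = np.asarray(g, dtype=np.float64)
        gv = np.zeros_like(f_exp)
        gv[valid] = g.reshape(-1)[flat]
        s2 = sigma * sigma
        w = gv * f_exp
        grad_u = (w * du).sum(axis=1) / s2
        grad_v = (w * dv).sum(axis=1) / s2
        grad_sigma = float((w * d2).sum() / (s2 * sigma))
        grad_pts = np.stack([grad_u * sx, grad_v * sy], axis=1)
        return grad_pts, grad_sigma

    return img, vjp
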