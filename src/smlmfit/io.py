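"""Readers and writers: localisation tables, TIFF stacks, image caches,
point clouds, YAML run configs and run logs.

All readers reject malformed input rather than silently coercing it, and
every writer/reader pair round-trips bit-exactly or to a stated tolerance.
Coordinates are 0-based with the pixel-centre convention throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import PointCloud3D
from .renderer import RenderConfig, RenderedImage, splat

__all__ = [
    "DegenerateInputError",
    "FormatError",
    "LocalisationSet",
    "PrerenderCache",
    "augment_cardinal",
    "prerender_cache",
    "read_image",
    "read_localisations",
    "read_pointcloud",
    "sum_project_stack",
    "write_image",
    "write_pointcloud",
    "load_config",
    "save_config",
    "write_run_log",
]


class FormatError(ValueError):
    """Malformed input file."""


class DegenerateInputError(ValueError):
    """Structurally valid input with no usable content (e.g. all zeros)."""


@dataclass
class LocalisationSet:
    """Per-structure 2D localisations in pixel units, centred on the
    structure centroid."""

    points: np.ndarray  # (M, 2), pixels
    scale: float  # nm per pixel (1.0 when native pixels)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 1:
            raise ValueError("points must be a non-empty (M, 2) array")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def read_localisations(
    path: str | Path, units: str = "px", scale: float = 1.0
) -> LocalisationSet:
    """Read a delimited x/y localisation table (header row, comma or tab).

    ``units='nm'`` divides coordinates by ``scale`` (nm per pixel).  The
    result is centred on the centroid.  Malformed rows raise
    :class:`FormatError` with the 1-based line number.
    """
    path = Path(path)
    if units not in ("px", "nm"):
        raise ValueError("units must be 'px' or 'nm'")
    if units == "nm" and scale <= 0:
        raise ValueError("nm units need a positive nm-per-pixel scale")
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error):
        raise FormatError(f"{path}: empty or undelimited localisation file") from None
    cols = {c.strip().lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise FormatError(f"{path}: need columns named 'x' and 'y', got {list(df.columns)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no localisation rows")
    xy = df[[cols["x"], cols["y"]]].apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.nonzero(~np.isfinite(xy).all(axis=1))[0]
    if bad.size:
        # +2: one for the header, one for 1-based numbering
        raise FormatError(f"{path}: non-numeric localisation at line {bad[0] + 2}")
    if units == "nm":
        xy = xy / scale
    xy = xy - xy.mean(axis=0)
    return LocalisationSet(xy, scale if units == "nm" else 1.0, source_id=path.stem)


def sum_project_stack(stack: np.ndarray, crop: int, z_axis: int = 0) -> np.ndarray:
    """Sum a 3D stack along z and centre-crop around the intensity centroid.

    The crop window is clamped to the frame so the output is always
    ``crop x crop``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"expected a 3D stack, got ndim={stack.ndim}")
    proj = stack.sum(axis=z_axis)
    h, w = proj.shape
    if crop > min(h, w) or crop < 1:
        raise ValueError(f"crop {crop} does not fit a {h}x{w} frame")
    total = float(proj.sum())
    if total <= 0:
        raise DegenerateInputError("all-zero stack has no intensity centroid")
    rows, cols = np.mgrid[0:h, 0:w]
    cy = float((rows * proj).sum() / total)
    cx = float((cols * proj).sum() / total)
    r0 = int(np.clip(np.floor(cy - crop / 2.0 + 0.5), 0, h - crop))
    c0 = int(np.clip(np.floor(cx - crop / 2.0 + 0.5), 0, w - crop))
    return proj[r0 : r0 + crop, c0 : c0 + crop]


def augment_cardinal(img: np.ndarray) -> list[np.ndarray]:
    """Lossless rotations of a square image by 0/90/180/270 degrees."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("cardinal augmentation needs a square 2D image")
    return [np.rot90(img, k).copy() for k in range(4)]


class PrerenderCache:
    """On-disk image cache keyed by (structure id, sigma).

    Images are stored as 32-bit float TIFFs named by a content hash of the
    key, so re-reads are bit-exact and distinct schedule sigmas are cached
    explicitly.
    """

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def key(source_id: str, sigma: float) -> str:
        return hashlib.sha1(f"{source_id}|{sigma:.9g}".encode()).hexdigest()[:16]

    def path(self, source_id: str, sigma: float) -> Path:
        return self.directory / f"{self.key(source_id, sigma)}.tiff"

    def put(self, source_id: str, sigma: float, pixels: np.ndarray) -> Path:
        p = self.path(source_id, sigma)
        tifffile.imwrite(p, np.asarray(pixels, dtype=np.float32))
        return p

    def get(self, source_id: str, sigma: float) -> np.ndarray:
        p = self.path(source_id, sigma)
        if not p.exists():
            raise KeyError(f"no cached image for ({source_id}, {sigma})")
        return tifffile.imread(p)

    def __len__(self) -> int:
        return len(list(self.directory.glob("*.tiff")))


def prerender_cache(
    localisations: list[LocalisationSet],
    sigmas,
    config: RenderConfig,
    directory: str | Path,
) -> PrerenderCache:
    """Render every structure at every distinct schedule sigma and store
    the images on disk; one cache entry per (structure, sigma) pair.

    ``sigmas`` is an iterable of pixel sigmas or a schedule object exposing
    ``values()`` (one sigma per epoch; duplicates collapse).
    """
    if hasattr(sigmas, "values") and not isinstance(sigmas, dict):
        sigmas = sigmas.values()
    sigmas = list(sigmas)
    cache = PrerenderCache(directory)
    ppw = config.pixels_per_world
    for loc in localisations:
        world = loc.points / ppw  # centred pixels -> world units
        for sigma in sorted(set(float(s) for s in sigmas)):
            img = splat(world, sigma, config)
            cache.put(loc.source_id, sigma, img.pixels)
    return cache


# ---------------------------------------------------------------------------
# point clouds and images


def write_pointcloud(points, path: str | Path, format: str | None = None) -> Path:
    """Write a cloud as ASCII PLY or XYZ; coordinates keep 9 significant
    digits so round trips recover them to 1e-6."""
    verts = points.vertices if isinstance(points, PointCloud3D) else np.asarray(points, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 3 or verts.shape[0] < 1:
        raise ValueError("need a non-empty (N, 3) cloud")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        lines = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(verts)}",
            "property float x",
            "property float y",
            "property float z",
            "end_header",
        ]
        lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in verts]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "xyz":
        path.write_text("\n".join(f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in verts) + "\n")
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r} (use 'ply' or 'xyz')")
    return path


def read_pointcloud(path: str | Path, label: str | None = None) -> PointCloud3D:
    """Read an ASCII PLY or XYZ vertex list."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty point-cloud file")
    lines = text.splitlines()
    if lines[0].strip() == "ply":
        try:
            n = next(
                int(l.split()[-1]) for l in lines if l.startswith("element vertex")
            )
            start = next(i for i, l in enumerate(lines) if l.strip() == "end_header") + 1
        except StopIteration:
            raise FormatError(f"{path}: malformed PLY header") from None
        rows = lines[start : start + n]
    else:
        rows = lines
    try:
        verts = np.array([[float(v) for v in r.split()[:3]] for r in rows])
    except (ValueError, IndexError) as e:
        raise FormatError(f"{path}: bad vertex record: {e}") from None
    return PointCloud3D(verts, label=label or path.stem)


def write_image(img: RenderedImage | np.ndarray, path: str | Path) -> Path:
    pixels = img.pixels if isinstance(img, RenderedImage) else img
    path = Path(path)
    tifffile.imwrite(path, np.asarray(pixels, dtype=np.float32))
    return path


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


# ---------------------------------------------------------------------------
# configs and logs


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def load_config(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: run config must be a YAML mapping")
    return data


def config_hash(config: dict) -> str:
    return hashlib.sha1(yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:12]


def write_run_log(
    path: str | Path, seed: int, config: dict, epoch_losses: list[tuple[float, float]]
) -> Path:
    """Plain-text run log: seed, config hash, then per-epoch train/test loss."""
    path = Path(path)
    lines = [f"seed\t{seed}", f"config_hash\t{config_hash(config)}", "epoch\ttrain_loss\ttest_loss"]
    lines += [f"{i}\t{tr:.8g}\t{te:.8g}" for i, (tr, te) in enumerate(epoch_losses)]
    path.write_text("\n".join(lines) + "\n")
    return path
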