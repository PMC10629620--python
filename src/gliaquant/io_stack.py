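"""Reading and writing confocal stacks, ROI polygons, and tables.

Conventions used throughout the package:

* volumes are indexed ``(z, y, x)``, 0-based, with half-open ranges;
* voxel spacing is ``(dz, dy, dx)`` in micrometres, supplied as metadata
  (default z interval 0.3 um, the acquisition step of the study design) and
  never inferred from TIFF tags;
* intensities are promoted to float64 on load without any rescaling, because
  every downstream readout is an integral of raw intensity.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path as _FsPath

import numpy as np
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

DEFAULT_SPACING = (0.3, 1.0, 1.0)


class GeometryError(ValueError):
    """Raised when stacks, ROIs, or masks have incompatible geometry."""


@dataclasses.dataclass(frozen=True)
class ImageStack:
    """One channel's 3D intensity volume plus voxel-spacing metadata.

    Parameters
    ----------
    voxels
        3D array indexed ``(z, y, x)``; finite, non-negative intensities.
    channel_name
        Label such as ``"lipid"``, ``"glia"`` or ``"neuron"``.
    spacing
        ``(dz, dy, dx)`` in micrometres; strictly positive.
    """

    voxels: np.ndarray
    channel_name: str = ""
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise GeometryError(f"voxels must be 3D (z, y, x), got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("intensities must be finite")
        if vox.min() < 0:
            raise ValueError("intensities must be non-negative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclasses.dataclass(frozen=True)
class ChannelSet:
    """A set of co-registered channels sharing shape and spacing."""

    channels: Mapping[str, ImageStack]

    def __post_init__(self) -> None:
        stacks = list(self.channels.values())
        if not stacks:
            raise ValueError("ChannelSet needs at least one channel")
        shape, spacing = stacks[0].shape, stacks[0].spacing
        for name, stk in self.channels.items():
            if stk.shape != shape:
                raise GeometryError(
                    f"shape mismatch: channel {name!r} is {stk.shape}, expected {shape}"
                )
            if stk.spacing != spacing:
                raise GeometryError(f"spacing mismatch on channel {name!r}")
        object.__setattr__(self, "channels", dict(self.channels))

    def __getitem__(self, name: str) -> ImageStack:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclasses.dataclass(frozen=True)
class Polygon2D:
    """Closed 2D polygon with ordered ``(y, x)`` vertices in pixel units.

    Must be simple (non-self-intersecting) and have at least 3 vertices;
    validity is checked with shapely on construction.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(y), float(x)) for y, x in self.vertices)
        if len(verts) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(verts)}")
        shp = _ShapelyPolygon([(x, y) for y, x in verts])
        if not shp.is_valid or shp.area == 0:
            raise ValueError("polygon is degenerate or self-intersecting")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=np.float64)

    @property
    def area(self) -> float:
        """Shoelace area in pixel^2."""
        v = self.as_array()
        y, x = v[:, 0], v[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def bounds(self) -> tuple[float, float, float, float]:
        """(ymin, xmin, ymax, xmax)."""
        v = self.as_array()
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())


@dataclasses.dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular ROI: 0-based origin, half-open extents."""

    origin: tuple[int, int]
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("RectROI extents must be strictly positive")

    def slices(self) -> tuple[slice, slice]:
        y0, x0 = self.origin
        return slice(y0, y0 + self.height), slice(x0, x0 + self.width)

    def check_within(self, shape_yx: tuple[int, int]) -> None:
        y0, x0 = self.origin
        if y0 < 0 or x0 < 0 or y0 + self.height > shape_yx[0] or x0 + self.width > shape_yx[1]:
            raise GeometryError(
                f"ROI {self} does not fit inside image of shape {shape_yx}"
            )


# ---------------------------------------------------------------------------
# point-in-polygon: the one geometric primitive whose boundary rule is
# contractual for the whole artifact (masks and polygon ROIs share it)
# ---------------------------------------------------------------------------

def points_in_polygon(polygon: Polygon2D, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test for pixel centers.

    The boundary is half-open: for an axis-aligned rectangle with integer
    vertices the low-y/low-x edges are inclusive and the high edges exclusive,
    so the number of included integer pixel centers equals the polygon's
    geometric area. This makes prism-mask voxel counts exactly
    area x z-extent on rectangles.
    """
    yy = np.asarray(yy, dtype=np.float64)
    xx = np.asarray(xx, dtype=np.float64)
    v = polygon.as_array()
    inside = np.zeros(np.broadcast(yy, xx).shape, dtype=bool)
    n = len(v)
    for i in range(n):
        y1, x1 = v[i]
        y2, x2 = v[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never cross the +x ray
        crosses = (y1 > yy) != (y2 > yy)
        x_int = x1 + (yy - y1) / (y2 - y1) * (x2 - x1)
        inside ^= crosses & (xx < x_int)
    return inside


def polygon_pixel_mask(polygon: Polygon2D, shape_yx: tuple[int, int]) -> np.ndarray:
    """Boolean (Y, X) raster of pixel centers inside ``polygon``."""
    yy, xx = np.meshgrid(
        np.arange(shape_yx[0], dtype=np.float64),
        np.arange(shape_yx[1], dtype=np.float64),
        indexing="ij",
    )
    return points_in_polygon(polygon, yy, xx)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_stack(path: str | _FsPath, channel_name: str = "",
               spacing: Sequence[float] = DEFAULT_SPACING) -> ImageStack:
    """Read a multi-page grayscale TIFF as a (z, y, x) stack."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise GeometryError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    return ImageStack(arr, channel_name=channel_name, spacing=tuple(spacing))


def write_stack(stack: ImageStack, path: str | _FsPath, dtype: str = "uint16") -> None:
    """Write a stack as a multi-page grayscale TIFF.

    Values must already fit the target integer dtype: no rescaling is done,
    so a write/read round trip preserves every voxel exactly.
    """
    info = np.iinfo(dtype)
    vox = stack.voxels
    if vox.max() > info.max or np.any(vox != np.round(vox)):
        raise ValueError(
            f"voxel values do not fit {dtype} losslessly; scale before writing"
        )
    tifffile.imwrite(str(path), vox.astype(dtype))


def read_channel_set(paths: Mapping[str, str | _FsPath],
                     spacing: Sequence[float] = DEFAULT_SPACING) -> ChannelSet:
    """Read one multi-page TIFF per channel into a co-registered ChannelSet."""
    channels = {
        name: read_stack(p, channel_name=name, spacing=spacing)
        for name, p in paths.items()
    }
    return ChannelSet(channels)  # shape/spacing agreement enforced here


def read_polygon(path: str | _FsPath) -> Polygon2D:
    """Read a polygon from plain text: one ``y x`` pair per line, '#' comments."""
    verts = []
    for lineno, raw in enumerate(_FsPath(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'y x', got {raw!r}")
        try:
            y, x = float(tokens[0]), float(tokens[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric token in {raw!r}") from exc
        verts.append((y, x))
    return Polygon2D(tuple(verts))


def write_polygon(polygon: Polygon2D, path: str | _FsPath) -> None:
    lines = [f"{y:.10g} {x:.10g}" for y, x in polygon.vertices]
    _FsPath(path).write_text("\n".join(lines) + "\n")
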