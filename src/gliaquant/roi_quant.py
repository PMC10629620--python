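"""Projection-and-ROI fluorescence quantification.

Summation projections over z followed by mean intensity / integrated density
inside a rectangular or freehand (polygon) ROI — the readout used for
reporter and immunostain levels (Ldh, Draper, tGPH, Stat92E, Dilp5). Pixel
inclusion uses the same center-of-pixel even-odd rule as the 3D glia mask.
No background subtraction and no rescaling anywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np

from .io_stack import (
    GeometryError,
    ImageStack,
    Polygon2D,
    RectROI,
    polygon_pixel_mask,
)


@dataclasses.dataclass(frozen=True)
class ProjectionImage:
    """2D summed-intensity image with provenance."""

    pixels: np.ndarray
    source_id: str = ""
    z_range: tuple[int, int] = (0, 0)

    @property
    def total(self) -> float:
        return float(self.pixels.sum())


@dataclasses.dataclass(frozen=True)
class RoiMeasurement:
    roi_id: str
    mean_intensity: float
    integrated_density: float
    pixel_count: int


def sum_projection(stack: ImageStack, z_range: tuple[int, int] | None = None,
                   source_id: str = "") -> ProjectionImage:
    """Exact per-pixel sum of the stack over a half-open z range."""
    nz = stack.shape[0]
    if z_range is None:
        z_range = (0, nz)
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= nz):
        raise GeometryError(f"empty or out-of-range z_range {z_range} for depth {nz}")
    return ProjectionImage(
        pixels=stack.voxels[z0:z1].sum(axis=0),
        source_id=source_id or stack.channel_name,
        z_range=(z0, z1),
    )


def roi_fingerprint(roi: RectROI | Polygon2D) -> str:
    """Stable hash of an ROI definition, for batch-consistency enforcement."""
    if isinstance(roi, RectROI):
        desc = f"rect:{roi.origin[0]},{roi.origin[1]},{roi.height},{roi.width}"
    else:
        desc = "poly:" + ";".join(f"{y:.10g},{x:.10g}" for y, x in roi.vertices)
    return hashlib.sha256(desc.encode()).hexdigest()[:16]


def measure_roi(projection: ProjectionImage, roi: RectROI | Polygon2D,
                roi_id: str | None = None) -> RoiMeasurement:
    """Mean intensity and integrated density over pixels inside the ROI."""
    img = projection.pixels
    if isinstance(roi, RectROI):
        roi.check_within(img.shape)
        patch = img[roi.slices()]
        values = patch.ravel()
    else:
        ymin, xmin, ymax, xmax = roi.bounds()
        if ymax < 0 or xmax < 0 or ymin > img.shape[0] - 1 or xmin > img.shape[1] - 1:
            raise GeometryError("polygon ROI lies outside the image")
        mask = polygon_pixel_mask(roi, img.shape)
        if not mask.any():
            raise GeometryError("ROI contains no pixel centers")
        values = img[mask]
    count = values.size
    total = float(values.sum())
    return RoiMeasurement(
        roi_id=roi_id or roi_fingerprint(roi),
        mean_intensity=total / count,
        integrated_density=total,
        pixel_count=count,
    )


class RoiBatch:
    """Measure one fixed ROI across a group of projections.

    The study kept ROI size and position identical across every image within
    an experiment; this helper enforces that by pinning the ROI fingerprint at
    construction and rejecting any other ROI unless ``allow_mixed=True``.
    """

    def __init__(self, roi: RectROI | Polygon2D, allow_mixed: bool = False):
        self.roi = roi
        self.fingerprint = roi_fingerprint(roi)
        self.allow_mixed = allow_mixed
        self.measurements: list[tuple[str, RoiMeasurement]] = []

    def measure(self, sample_id: str, projection: ProjectionImage,
                roi: RectROI | Polygon2D | None = None) -> RoiMeasurement:
        use = self.roi if roi is None else roi
        if roi_fingerprint(use) != self.fingerprint and not self.allow_mixed:
            raise ValueError(
                "ROI differs from the batch definition; pass allow_mixed=True "
                "to permit per-sample ROIs"
            )
        m = measure_roi(projection, use)
        self.measurements.append((sample_id, m))
        return m
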