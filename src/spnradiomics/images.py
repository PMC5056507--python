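"""Image/mask containers, raster I/O and ROI handling.

Images are single 2-D CT slices on the Hounsfield-unit (HU) scale with
per-axis pixel spacing in millimetres.  Masks are binary rasters aligned
pixel-for-pixel with an image.  An ROI drawn around a nodule outline is
*refined* by an attenuation window before any feature is computed: pixels
whose original HU falls below ``lo`` or above ``hi`` (defaults −50 and
300 HU) are dropped, which removes air and calcification from the region.

On disk an image is a 16-bit TIFF plus a JSON sidecar carrying spacing and
metadata, or a single-frame DICOM; masks are 8-bit binary TIFFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

__all__ = [
    "ImageSlice",
    "ROIMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "refine_roi",
    "roi_geometry",
]

HU_WINDOW = (-50.0, 300.0)


@dataclass
class ImageSlice:
    """A 2-D intensity raster in HU with pixel spacing in mm."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ImageSlice requires a 2-D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageSlice intensities must be finite")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if min(self.spacing) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ROIMask:
    """Binary region of interest aligned to an :class:`ImageSlice`."""

    mask: np.ndarray
    refined: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) > 0
        if self.mask.ndim != 2:
            raise ValueError("ROIMask requires a 2-D array")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(image: ImageSlice, path: str | Path) -> Path:
    """Write a slice as int16 TIFF with a JSON sidecar; returns the path.

    Intensities are rounded to integer HU, so integer-valued images
    round-trip exactly.
    """
    import tifffile

    path = Path(path)
    data = np.rint(image.pixels).astype(np.int16)
    tifffile.imwrite(path, data)
    sidecar = {
        "spacing_mm": list(image.spacing),
        "hu_offset": 0,
        **{k: v for k, v in image.meta.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def _read_tiff(path: Path) -> ImageSlice:
    import tifffile

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"TIFF image {path} needs a JSON sidecar at {sidecar} "
            "(spacing_mm, hu_offset)"
        )
    meta = json.loads(sidecar.read_text())
    pixels = tifffile.imread(path).astype(float) + float(meta.get("hu_offset", 0))
    spacing = tuple(meta.pop("spacing_mm", (1.0, 1.0)))
    meta.pop("hu_offset", None)
    return ImageSlice(pixels=pixels, spacing=spacing, meta=meta)


def _read_dicom(path: Path) -> ImageSlice:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame DICOM")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = arr * slope + intercept
    spacing = tuple(float(s) for s in getattr(ds, "PixelSpacing", [1.0, 1.0]))
    meta = {"sop_instance_uid": str(getattr(ds, "SOPInstanceUID", ""))}
    return ImageSlice(pixels=pixels, spacing=spacing, meta=meta)


def read_image(path: str | Path) -> ImageSlice:
    """Read a TIFF(+sidecar) or single-frame DICOM slice as HU values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return _read_tiff(path)
    if suffix in {".dcm", ".dicom"}:
        return _read_dicom(path)
    raise ValueError(f"unknown image format {suffix!r} for {path}")


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8)) * 255)
    return path


def read_mask(path: str | Path, refined: bool = False) -> ROIMask:
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return ROIMask(mask=tifffile.imread(path) > 0, refined=refined)


def refine_roi(
    image: ImageSlice,
    mask: ROIMask,
    lo: float = HU_WINDOW[0],
    hi: float = HU_WINDOW[1],
) -> ROIMask:
    """Restrict the ROI to pixels whose original HU lies in [lo, hi].

    Bounds are inclusive: attenuation strictly below ``lo`` (air) or
    strictly above ``hi`` (bone/calcification) is excluded.  The input
    mask is untouched; the refinement always re-applies the window to the
    original HU values, so it is idempotent and monotone in the window.
    """
    if mask.mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    window = (image.pixels >= lo) & (image.pixels <= hi)
    refined = mask.mask & window
    if not refined.any():
        raise ValueError(
            f"ROI is empty after the [{lo}, {hi}] HU window: the region "
            "contains only air/bone-range attenuation"
        )
    return ROIMask(mask=refined, refined=True)


def roi_geometry(image: ImageSlice, mask: ROIMask) -> tuple[float, float]:
    """Return (area in mm^2, maximum diameter in mm) of the mask.

    Area is the pixel count times the pixel-spacing product; the diameter
    is the largest pairwise distance between in-mask pixel centres.
    """
    if not mask.mask.any():
        raise ValueError("cannot measure geometry of an empty mask")
    if mask.mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    sr, sc = image.spacing
    rows, cols = np.nonzero(mask.mask)
    area = rows.size * sr * sc
    pts = np.column_stack([rows * sr, cols * sc])
    if pts.shape[0] == 1:
        return area, 0.0
    # the diameter is attained on the convex hull; fall back to all points
    # for tiny or collinear masks where hull construction fails
    if pts.shape[0] > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    return area, float(pdist(pts).max())


def translate_mask(mask: ROIMask, shift: tuple[int, int]) -> ROIMask:
    """Shift a mask by whole pixels (testing utility; no wrap-around)."""
    out = np.zeros_like(mask.mask)
    dr, dc = shift
    src = mask.mask
    rows, cols = np.nonzero(src)
    rows, cols = rows + dr, cols + dc
    keep = (rows >= 0) & (rows < src.shape[0]) & (cols >= 0) & (cols < src.shape[1])
    out[rows[keep], cols[keep]] = True
    return replace(mask, mask=out)
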