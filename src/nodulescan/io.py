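"""Image and table I/O.

PNG/TIFF are handled with imageio/tifffile.  HU rasters persisted outside
DICOM are stored as 16-bit TIFF with a +1024 offset (so -1024 HU maps to 0);
the offset is re-subtracted on read.  DICOM is supported when pydicom is
importable (optional extra), recovering HU via rescale slope/intercept.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import tifffile

from .image import GrayImage, SpacingInfo

__all__ = ["read_image", "write_image", "write_mask", "HU_TIFF_OFFSET"]

HU_TIFF_OFFSET = 1024


class ImageFormatError(ValueError):
    pass


def _read_dicom(path: str, spacing: SpacingInfo | None) -> GrayImage:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImageFormatError(f"{path}: reading DICOM requires the optional pydicom dependency") from exc
    ds = pydicom.dcmread(path)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    px = ds.pixel_array.astype(float) * slope + intercept
    if spacing is None:
        ps = getattr(ds, "PixelSpacing", None)
        spacing = SpacingInfo(float(ps[0]), float(ps[1])) if ps else SpacingInfo(1.0, 1.0)
    return GrayImage(px, value_domain="HU", spacing=spacing)


def read_image(path: str, spacing: SpacingInfo | None = None, hu_offset: bool | None = None) -> GrayImage:
    """Read DICOM / PNG / TIFF into a GrayImage.

    8-bit rasters are tagged uint8 domain; 16-bit TIFFs are assumed to carry
    HU + 1024 unless ``hu_offset=False``.  ``spacing`` overrides (or stands
    in for) file metadata.
    """
    if not os.path.exists(path):
        raise ImageFormatError(f"no such image file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".dcm", ".dicom"):
        return _read_dicom(path, spacing)
    if ext not in (".png", ".tif", ".tiff"):
        raise ImageFormatError(f"{path}: unsupported image format {ext!r}")
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]  # grayscale stored with redundant channels
    spacing = spacing or SpacingInfo(1.0, 1.0)
    if arr.dtype == np.uint8:
        return GrayImage(arr.astype(float), value_domain="uint8", spacing=spacing)
    offset = HU_TIFF_OFFSET if (hu_offset is None or hu_offset) else 0
    return GrayImage(arr.astype(float) - offset, value_domain="HU", spacing=spacing)


def write_image(path: str, image: GrayImage) -> None:
    """Write uint8 images as PNG/TIFF; HU images as 16-bit TIFF (+1024)."""
    ext = os.path.splitext(path)[1].lower()
    if image.value_domain == "uint8":
        data = np.clip(np.floor(np.asarray(image.pixels, dtype=float) + 0.5), 0, 255).astype(np.uint8)
        iio.imwrite(path, data)
        return
    if ext not in (".tif", ".tiff"):
        raise ImageFormatError("HU images must be written as 16-bit TIFF")
    data = np.clip(np.round(np.asarray(image.pixels, dtype=float)) + HU_TIFF_OFFSET, 0, 65535)
    tifffile.imwrite(path, data.astype(np.uint16))


def write_mask(path: str, mask: np.ndarray) -> None:
    """Binary mask as 8-bit PNG with values {0, 255}."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
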