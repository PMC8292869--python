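"""Raster and tabular I/O for the effusion texture pipeline.

Coordinate convention (fixed package-wide): arrays are indexed ``(row, col)``,
0-based, row 0 at the top.  Pixel offsets elsewhere in the package are
expressed as ``(dx, dy)`` = (column offset rightward, row offset downward).

Supported formats: single-frame grayscale DICOM (Hounsfield rescale applied
when the RescaleSlope/RescaleIntercept tags are present), 8/16-bit grayscale
PNG/TIFF for images and masks, CSV for cohort manifests and feature tables.
Readers reject malformed input rather than silently coercing it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image as PILImage

__all__ = [
    "GrayImage",
    "ROIMask",
    "EmptyROIError",
    "LabelError",
    "read_dicom_slice",
    "write_dicom_slice",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_feature_table",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ("image_path", "mask_path", "label")


class EmptyROIError(ValueError):
    """Raised when a mask contains no foreground pixels."""


class LabelError(ValueError):
    """Raised when a cohort does not carry exactly two class labels."""


@dataclass
class GrayImage:
    """A 2-D grayscale raster with optional physical calibration.

    Parameters
    ----------
    pixels
        2-D float array of intensities (HU if calibrated).
    spacing
        Optional (row, col) pixel spacing in mm.
    calibration
        Optional (slope, intercept) that was applied to the stored values.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] | None = None
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError("GrayImage requires a 2-D raster of at least 2x2 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ROIMask:
    """A binary region-of-interest raster aligned to a :class:`GrayImage`."""

    pixels: np.ndarray = field()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels) != 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    def require_nonempty(self) -> None:
        if self.n_foreground == 0:
            raise EmptyROIError("ROI mask has no foreground pixels")


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_slice(path: str | os.PathLike) -> GrayImage:
    """Read a single-frame grayscale DICOM slice.

    Stored values are mapped through ``value * RescaleSlope + RescaleIntercept``
    when those tags exist (the standard HU calibration); otherwise the raw
    stored values are returned.  MONOCHROME1 images are inverted on read so
    that higher pixel value always means brighter.
    """
    import pydicom

    ds = pydicom.dcmread(os.fspath(path))
    if "PixelData" not in ds:
        raise ValueError(f"{path}: DICOM file has no pixel data")
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise ValueError(f"{path}: multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise ValueError(f"{path}: color DICOM is not supported")

    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    calibration = None
    if "RescaleSlope" in ds or "RescaleIntercept" in ds:
        arr = arr * slope + intercept
        calibration = (slope, intercept)

    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        # invert polarity about the observed range
        arr = arr.max() + arr.min() - arr

    spacing = None
    if "PixelSpacing" in ds:
        ps = ds.PixelSpacing
        spacing = (float(ps[0]), float(ps[1]))
    return GrayImage(arr, spacing=spacing, calibration=calibration)


def write_dicom_slice(
    pixels: np.ndarray,
    path: str | os.PathLike,
    *,
    slope: float = 1.0,
    intercept: float = 0.0,
    spacing: tuple[float, float] | None = None,
) -> None:
    """Write an integer raster as a minimal single-frame grayscale DICOM.

    The raster holds *stored* values; ``slope``/``intercept`` are written as
    rescale tags so that a round-trip through :func:`read_dicom_slice` yields
    ``pixels * slope + intercept``.  Intended for fixtures and interchange.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("write_dicom_slice expects a 2-D raster")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("write_dicom_slice expects integer stored values")
    if arr.min() < 0:
        stored = arr.astype(np.int16)
        pixel_representation = 1
    else:
        stored = arr.astype(np.uint16)
        pixel_representation = 0

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(os.fspath(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = pixel_representation
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    if spacing is not None:
        ds.PixelSpacing = [spacing[0], spacing[1]]
    ds.PixelData = stored.tobytes()
    ds.save_as(os.fspath(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# PNG / TIFF rasters
# ---------------------------------------------------------------------------

def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a grayscale PNG/TIFF raster."""
    with PILImage.open(os.fspath(path)) as im:
        if im.mode not in ("L", "I", "I;16", "F"):
            im = im.convert("I")
        arr = np.asarray(im, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a grayscale raster")
    return GrayImage(arr)


def write_image(pixels: np.ndarray, path: str | os.PathLike) -> None:
    """Write an integer raster as 8- or 16-bit grayscale PNG/TIFF."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("expected integer pixel values (quantize before writing)")
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("pixel values outside the 16-bit unsigned range")
    if arr.max() <= 255:
        PILImage.fromarray(arr.astype(np.uint8), mode="L").save(os.fspath(path))
    else:
        PILImage.fromarray(arr.astype(np.uint16)).save(os.fspath(path))


def read_mask(path: str | os.PathLike, image: GrayImage | None = None) -> ROIMask:
    """Read a binary mask raster; nonzero pixels are foreground.

    If ``image`` is given the mask shape must match it; an empty mask is
    rejected because downstream texture statistics are undefined on it.
    """
    with PILImage.open(os.fspath(path)) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a grayscale mask raster")
    mask = ROIMask(arr)
    if image is not None and mask.shape != image.shape:
        raise ValueError(
            f"{path}: mask shape {mask.shape} does not match image shape {image.shape}"
        )
    mask.require_nonempty()
    return mask


def write_mask(mask: ROIMask, path: str | os.PathLike) -> None:
    """Write a mask as an 8-bit PNG (foreground = 255)."""
    write_image(mask.pixels.astype(np.uint8) * 255, path)


# ---------------------------------------------------------------------------
# Manifests and feature tables
# ---------------------------------------------------------------------------

def read_manifest(path: str | os.PathLike, *, check_files: bool = True) -> pd.DataFrame:
    """Read a cohort manifest CSV with columns image_path, mask_path, label.

    Relative paths are resolved against the manifest's directory.  Exactly two
    distinct labels are required (the analysis is a two-class comparison).
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty cohort manifest")
    labels = df["label"].unique()
    if len(labels) != 2:
        raise LabelError(
            f"{path}: expected exactly 2 distinct labels, found {len(labels)}: {sorted(map(str, labels))}"
        )
    base = os.path.dirname(os.fspath(path))
    for col in ("image_path", "mask_path"):
        df[col] = [
            p if os.path.isabs(p) else os.path.join(base, p) for p in df[col].astype(str)
        ]
        if check_files:
            for p in df[col]:
                if not os.path.exists(p):
                    raise FileNotFoundError(f"{path}: referenced file not found: {p}")
    return df.reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a feature table CSV: sample_id, label, then features in order."""
    lead = ["sample_id", "label"]
    missing = [c for c in lead if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    rest = [c for c in table.columns if c not in lead]
    table[lead + rest].to_csv(path, index=False)
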