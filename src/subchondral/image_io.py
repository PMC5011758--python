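"""Calibrated image I/O, bone segmentation and BMD calibration.

Images are 2D 8-bit grayscale micro-CT cross sections of the osteochondral
unit.  The row index is depth (increasing downward, toward the subarticular
spongiosa), the column index is the horizontal position along the joint
surface.  Every physical quantity downstream is expressed in millimetres, so
each image carries an explicit isotropic pixel size.  The physical coordinate
of a pixel is its centre: ``x = (col + 0.5) * pixel_size_mm`` and
``depth = (row + 0.5) * pixel_size_mm``.

Bone is segmented by a closed gray-value interval (default 89-255, the
standard bone window for these scans) and gray values are mapped to bone
mineral density through a two-point calibration against hydroxyapatite
phantom rods of known density (250 and 750 mg CaHA/cm^3).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "GrayThreshold",
    "BmdCalibration",
    "AnnotationSet",
    "AnnotationError",
    "read_image",
    "read_stack",
    "write_image",
    "segment_bone",
    "gray_to_bmd",
    "read_annotations",
    "write_annotations",
]


class AnnotationError(ValueError):
    """Raised when an annotation file violates the documented schema."""


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D 8-bit grayscale raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Gray values; row index is depth (downward), column index horizontal.
    pixel_size_mm : float
        Physical side length of one (isotropic) pixel in mm.
    slice_id : int, optional
        Position within a consecutive image stack.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    slice_id: Optional[int] = None

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2 or pix.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if pix.dtype != np.uint8:
            if pix.min() < 0 or pix.max() > 255:
                raise ValueError("gray values must lie in [0, 255]")
            pix = pix.astype(np.uint8)
        object.__setattr__(self, "pixels", pix)
        if not (self.pixel_size_mm > 0):
            raise ValueError("pixel_size_mm must be > 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def height_mm(self) -> float:
        return self.pixels.shape[0] * self.pixel_size_mm

    @property
    def width_mm(self) -> float:
        return self.pixels.shape[1] * self.pixel_size_mm


@dataclass(frozen=True)
class BinaryMask:
    """Boolean bone mask with the same shape and calibration as its source."""

    pixels: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels, dtype=bool)
        if pix.ndim != 2 or pix.size == 0:
            raise ValueError("mask must be a non-empty 2D boolean array")
        object.__setattr__(self, "pixels", pix)
        if not (self.pixel_size_mm > 0):
            raise ValueError("pixel_size_mm must be > 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GrayThreshold:
    """Closed gray-value interval considered bone (both bounds inclusive)."""

    lo: int = 89
    hi: int = 255

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 255):
            raise ValueError("require 0 <= lo <= hi <= 255")


@dataclass(frozen=True)
class BmdCalibration:
    """Two-point gray -> bone mineral density calibration.

    ``gray_lo``/``gray_hi`` are the mean gray values measured in the
    low- and high-density hydroxyapatite rods; the rod densities default to
    the standard 250 and 750 mg CaHA/cm^3 pair.
    """

    gray_lo: float
    gray_hi: float
    bmd_lo: float = 250.0
    bmd_hi: float = 750.0

    def __post_init__(self) -> None:
        if self.gray_lo == self.gray_hi:
            raise ValueError("degenerate calibration: gray_lo == gray_hi")
        if not (self.bmd_lo < self.bmd_hi):
            raise ValueError("require bmd_lo < bmd_hi")


@dataclass(frozen=True)
class AnnotationSet:
    """Manual annotations accompanying an image or stack.

    ``cement_line`` holds two (x, depth) endpoints in mm of the projected
    cement line drawn by a rater; when absent the line is estimated from the
    flanking intact plate.  ``defect_extent_mm`` is the horizontal interval
    [x_left, x_right] of the defect; when absent it is auto-detected.
    """

    cement_line: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None
    defect_extent_mm: Optional[Tuple[float, float]] = None
    awl: Optional["AwlSpec"] = None  # noqa: F821 - forward ref to phantom.AwlSpec

    def __post_init__(self) -> None:
        if self.cement_line is not None:
            (x1, y1), (x2, y2) = self.cement_line
            if (x1, y1) == (x2, y2):
                raise AnnotationError("cement line endpoints must be distinct")
            if x1 == x2:
                raise AnnotationError("cement line endpoints must differ in x")
        if self.defect_extent_mm is not None:
            left, right = self.defect_extent_mm
            if not (left < right):
                raise AnnotationError("defect extent requires x_left < x_right")


def read_image(path, pixel_size_mm: float, slice_id: Optional[int] = None) -> CalibratedImage:
    """Read a single-channel 8-bit raster (PNG or TIFF) with calibration.

    Multi-channel inputs are converted to gray by ITU-R 601 luminance and a
    warning is logged.  The pixel size is supplied by the caller because
    raster formats carry resolution metadata inconsistently.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not (pixel_size_mm > 0):
        raise ValueError("pixel_size_mm must be > 0")
    try:
        arr = np.asarray(iio.imread(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file: {path}") from exc
    if arr.ndim == 3:
        logger.warning("multi-channel image %s converted to gray by luminance", path)
        rgb = arr[..., :3].astype(np.float64)
        arr = np.rint(rgb @ np.array([0.299, 0.587, 0.114])).astype(np.uint8)
    if arr.ndim != 2:
        raise OSError(f"cannot interpret {path} as a 2D gray image")
    if arr.dtype != np.uint8:
        if arr.max(initial=0) > 255:
            raise OSError(f"{path}: only 8-bit gray rasters are supported")
        arr = arr.astype(np.uint8)
    return CalibratedImage(arr, pixel_size_mm, slice_id=slice_id)


def read_stack(path, pixel_size_mm: float) -> list[CalibratedImage]:
    """Read a multi-page TIFF as a stack of calibrated slices."""
    import tifffile

    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF stack: {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise OSError(f"cannot interpret {path} as a gray image stack")
    return [
        CalibratedImage(arr[i].astype(np.uint8), pixel_size_mm, slice_id=i)
        for i in range(arr.shape[0])
    ]


def write_image(path, image: CalibratedImage) -> None:
    """Write an 8-bit gray raster; format chosen from the file suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image.pixels)


def write_stack(path, images: Sequence[CalibratedImage]) -> None:
    """Write a stack of slices as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(
        Path(path), np.stack([im.pixels for im in images]), photometric="minisblack"
    )


def segment_bone(image: CalibratedImage, thr: GrayThreshold = GrayThreshold()) -> BinaryMask:
    """Binarize bone: true exactly where ``thr.lo <= gray <= thr.hi``."""
    pix = image.pixels
    return BinaryMask((pix >= thr.lo) & (pix <= thr.hi), image.pixel_size_mm)


def gray_to_bmd(gray, calib: BmdCalibration):
    """Map gray value(s) to bone mineral density (mg CaHA/cm^3).

    The two rod points define a global line; values outside the rod range are
    extrapolated (with a logged warning) rather than clipped.
    """
    gray = np.asarray(gray, dtype=float)
    slope = (calib.bmd_hi - calib.bmd_lo) / (calib.gray_hi - calib.gray_lo)
    bmd = calib.bmd_lo + slope * (gray - calib.gray_lo)
    lo, hi = min(calib.bmd_lo, calib.bmd_hi), max(calib.bmd_lo, calib.bmd_hi)
    if np.any(bmd < lo) or np.any(bmd > hi):
        logger.warning("gray value outside rod calibration range; extrapolating")
    return float(bmd) if bmd.ndim == 0 else bmd


_ANNOTATION_KEYS = {"cement_line", "defect_extent_mm", "awl"}


def read_annotations(path) -> AnnotationSet:
    """Parse a JSON annotation file.

    Schema (all keys optional)::

        {
          "cement_line": [[x1_mm, depth1_mm], [x2_mm, depth2_mm]],
          "defect_extent_mm": [x_left_mm, x_right_mm],
          "awl": {"diameter_mm": 1.2, "penetration_depth_mm": 2.0}
        }
    """
    from .phantom import AwlSpec

    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"cannot parse annotation file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise AnnotationError("annotation file must contain a JSON object")
    bad = sorted(set(data) - _ANNOTATION_KEYS)
    if bad:
        raise AnnotationError(f"unknown annotation keys: {bad}")

    cement = None
    if data.get("cement_line") is not None:
        raw = data["cement_line"]
        try:
            (x1, y1), (x2, y2) = raw
            cement = ((float(x1), float(y1)), (float(x2), float(y2)))
        except (TypeError, ValueError) as exc:
            raise AnnotationError("offending key 'cement_line': expected two [x, depth] points") from exc
    extent = None
    if data.get("defect_extent_mm") is not None:
        raw = data["defect_extent_mm"]
        try:
            left, right = (float(raw[0]), float(raw[1]))
        except (TypeError, ValueError, IndexError) as exc:
            raise AnnotationError("offending key 'defect_extent_mm': expected [x_left, x_right]") from exc
        if not (left < right):
            raise AnnotationError("offending key 'defect_extent_mm': x_left must be < x_right")
        extent = (left, right)
    awl = None
    if data.get("awl") is not None:
        raw = data["awl"]
        try:
            awl = AwlSpec(float(raw["diameter_mm"]), float(raw["penetration_depth_mm"]))
        except (TypeError, KeyError, ValueError) as exc:
            raise AnnotationError("offending key 'awl': expected diameter_mm and penetration_depth_mm") from exc
    try:
        return AnnotationSet(cement_line=cement, defect_extent_mm=extent, awl=awl)
    except AnnotationError:
        raise
    except ValueError as exc:
        raise AnnotationError(str(exc)) from exc


def write_annotations(path, annotations: AnnotationSet) -> None:
    data: dict = {}
    if annotations.cement_line is not None:
        data["cement_line"] = [list(p) for p in annotations.cement_line]
    if annotations.defect_extent_mm is not None:
        data["defect_extent_mm"] = list(annotations.defect_extent_mm)
    if annotations.awl is not None:
        data["awl"] = {
            "diameter_mm": annotations.awl.diameter_mm,
            "penetration_depth_mm": annotations.awl.penetration_depth_mm,
        }
    Path(path).write_text(json.dumps(data, indent=2))
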