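"""Reading CT slices, display-scale windowing and overlay output.

CT attenuation is kept in Hounsfield units (HU) for as long as possible;
all perceptual processing (contrast curve, region statistics) happens on a
display-scale [0, 255] image produced by a linear brain window.  DICOM input
is rescaled to HU via the slope/intercept tags; 8-bit PNG input is treated
as already display-scaled pseudo-HU, which keeps fixture-driven tests free
of any DICOM machinery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pydicom

from .errors import InputError, ParameterError, UnsupportedFormatError

DEFAULT_SPACING_MM = 0.2

#: standard non-contrast brain window (HU)
DEFAULT_WINDOW_CENTER = 35.0
DEFAULT_WINDOW_WIDTH = 80.0


@dataclass
class CTSlice:
    """A single calibrated axial CT slice.

    Attributes
    ----------
    pixels : 2-D float array of attenuation values in HU.
    spacing_mm : pixel edge length in millimetres (square pixels assumed).
    """

    pixels: np.ndarray
    spacing_mm: float = DEFAULT_SPACING_MM
    source: str = field(default="", compare=False)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("CTSlice requires a non-empty 2-D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("CTSlice pixels must be finite HU values")
        if self.spacing_mm <= 0:
            raise ParameterError("spacing_mm must be positive")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    def pixel_area_mm2(self) -> float:
        return self.spacing_mm ** 2


def _read_dicom(path: str) -> CTSlice:
    ds = pydicom.dcmread(path)
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise UnsupportedFormatError("multi-frame DICOM input is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError("color DICOM input is not supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(np.float64) * slope + intercept
    spacing = DEFAULT_SPACING_MM
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None and len(ps) >= 1:
        spacing = float(ps[0])
    return CTSlice(hu, spacing_mm=spacing, source=os.fspath(path))


def _read_png(path: str) -> CTSlice:
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise UnsupportedFormatError("color PNG input is not supported")
    return CTSlice(arr.astype(np.float64), spacing_mm=DEFAULT_SPACING_MM,
                   source=os.fspath(path))


def read_ct(path) -> CTSlice:
    """Read a single-frame grayscale DICOM or PNG slice.

    DICOM stored values are rescaled to HU with the RescaleSlope and
    RescaleIntercept tags; PNG values pass through unchanged as pseudo-HU
    with the default 0.2 mm pixel spacing.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    lower = path.lower()
    if lower.endswith(".png"):
        return _read_png(path)
    try:
        return _read_dicom(path)
    except UnsupportedFormatError:
        raise
    except Exception:
        pass
    try:
        return _read_png(path)
    except UnsupportedFormatError:
        raise
    except Exception as exc:
        raise InputError(f"could not read {path} as DICOM or PNG: {exc}") from exc


def to_display(ct: CTSlice, window_center: float = DEFAULT_WINDOW_CENTER,
               window_width: float = DEFAULT_WINDOW_WIDTH) -> np.ndarray:
    """Map HU to the display scale [0, 255] with a linear window.

    ``center - width/2`` maps to 0 and ``center + width/2`` to 255; values
    outside the window clamp.  The map is monotone non-decreasing in HU.
    """
    if window_width <= 0:
        raise ParameterError("window_width must be positive")
    lo = window_center - window_width / 2.0
    scaled = (ct.pixels - lo) / window_width
    return np.clip(scaled, 0.0, 1.0) * 255.0


def hu_to_display_value(hu: float, window_center: float = DEFAULT_WINDOW_CENTER,
                        window_width: float = DEFAULT_WINDOW_WIDTH) -> float:
    """Display-scale value a single HU level maps to under :func:`to_display`."""
    if window_width <= 0:
        raise ParameterError("window_width must be positive")
    lo = window_center - window_width / 2.0
    return float(np.clip((hu - lo) / window_width, 0.0, 1.0) * 255.0)


def write_overlay(img: np.ndarray, path) -> None:
    """Write an RGB overlay image as lossless 8-bit PNG."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputError("overlay must be an RGB (rows, cols, 3) array")
    try:
        iio.imwrite(os.fspath(path), np.clip(np.round(img), 0, 255).astype(np.uint8))
    except OSError as exc:
        raise InputError(f"cannot write overlay to {path}: {exc}") from exc


def write_gray_png(img: np.ndarray, path, bitdepth16: bool = False) -> None:
    """Write a grayscale image (display scale, or 16-bit for label maps)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise InputError("expected a 2-D grayscale array")
    if bitdepth16:
        iio.imwrite(os.fspath(path), np.clip(np.round(img), 0, 65535).astype(np.uint16))
    else:
        iio.imwrite(os.fspath(path), np.clip(np.round(img), 0, 255).astype(np.uint8))
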