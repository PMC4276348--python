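"""Synthetic axial brain-CT phantom with planted ischemic lesion.

The phantom is a stylised head slice in Hounsfield units: an elliptical
skull ring (~1000 HU) around brain tissue, a peripheral gray-matter mantle
(brighter, higher cell density) over a deep white-matter core (darker) at
half the brain semi-axes, small paired ventricles of cerebrospinal fluid,
and additive Gaussian noise.  An optional circular hypodense lesion in the
stroke attenuation range (30-36 HU) is planted at the gray-white interface
on the horizontal midline — offset outward so it sits predominantly in gray
matter, where ischemic infarcts are most common, and straddling the
upper/lower region boundary, mirroring the clinical observation that
infarcts typically span two of the eight partition regions.

Every voxel of the ground truth (brain, skull, lesion masks) is returned,
so all pipeline stages can be scored without patient data.  Generation is
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io_formats import CTSlice

AIR_HU = -1000.0

# geometry as fractions of the image side
_BRAIN_SEMI_ROW = 0.40
_BRAIN_SEMI_COL = 0.34
_SKULL_THICKNESS = 0.035
_WHITE_CORE_RATIO = 0.5      # white-matter core at half the brain semi-axes
_VENTRICLE_SEMI_ROW = 0.12   # of the brain semi-row
_VENTRICLE_SEMI_COL = 0.05   # of the brain semi-col
_VENTRICLE_OFFSET = 0.18     # of the brain semi-col, either side of midline


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; defaults are the study conditions."""

    size: int = 512
    spacing_mm: float = 0.2
    skull_hu: float = 1000.0
    gray_hu: float = 40.0
    white_hu: float = 25.0
    csf_hu: float = 8.0
    noise_sd: float = 1.5
    lesion_side: str = "left"        # "left", "right" or "none"
    lesion_area_mm2: float = 27.5
    lesion_hu: float = 32.0
    ventricles: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.size < 64:
            raise ParameterError("phantom size must be at least 64")
        if self.spacing_mm <= 0:
            raise ParameterError("spacing_mm must be positive")
        if self.lesion_side not in ("left", "right", "none"):
            raise ParameterError("lesion_side must be 'left', 'right' or 'none'")
        if self.lesion_area_mm2 <= 0:
            raise ParameterError("lesion_area_mm2 must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """Ground-truth masks for scoring the pipeline."""

    brain_mask: np.ndarray
    skull_mask: np.ndarray
    lesion_mask: np.ndarray
    lesion_side: str

    def to_json(self, path) -> None:
        payload = {
            "lesion_side": self.lesion_side,
            "brain_pixels": int(self.brain_mask.sum()),
            "lesion_pixels": int(self.lesion_mask.sum()),
            "brain_mask_rle": _rle_encode(self.brain_mask),
            "skull_mask_rle": _rle_encode(self.skull_mask),
            "lesion_mask_rle": _rle_encode(self.lesion_mask),
            "shape": list(self.brain_mask.shape),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Flat run-length encoding (starts with the run of zeros)."""
    flat = np.asarray(mask, bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate(([0], changes, [flat.size])))
    if flat[0]:
        return [0] + runs.tolist()
    return runs.tolist()


def _ellipse(rr, cc, center, semi_row, semi_col) -> np.ndarray:
    return (((rr - center[0]) / semi_row) ** 2
            + ((cc - center[1]) / semi_col) ** 2) <= 1.0


def _lesion_disk(shape, center, n_pixels: int) -> np.ndarray:
    """Disk of exactly ``n_pixels`` pixels: the n closest grid points to the
    center, ties broken lexicographically for determinism."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    order = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[order[:n_pixels]] = True
    return mask


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[CTSlice, PhantomTruth]:
    """Build the phantom slice and its ground truth."""
    n = spec.size
    rr, cc = np.mgrid[0:n, 0:n]
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    b_row = _BRAIN_SEMI_ROW * n
    b_col = _BRAIN_SEMI_COL * n
    skull_out_row = b_row + _SKULL_THICKNESS * n
    skull_out_col = b_col + _SKULL_THICKNESS * n

    brain = _ellipse(rr, cc, center, b_row, b_col)
    skull = _ellipse(rr, cc, center, skull_out_row, skull_out_col) & ~brain
    white = _ellipse(rr, cc, center, _WHITE_CORE_RATIO * b_row,
                     _WHITE_CORE_RATIO * b_col)

    hu = np.full((n, n), AIR_HU)
    hu[skull] = spec.skull_hu
    hu[brain] = spec.gray_hu
    hu[white] = spec.white_hu

    if spec.ventricles:
        v_row = _VENTRICLE_SEMI_ROW * b_row
        v_col = _VENTRICLE_SEMI_COL * b_col
        for sign in (-1.0, 1.0):
            v_center = (center[0], center[1] + sign * _VENTRICLE_OFFSET * b_col)
            hu[_ellipse(rr, cc, v_center, v_row, v_col) & brain] = spec.csf_hu

    lesion = np.zeros((n, n), dtype=bool)
    if spec.lesion_side != "none":
        n_px = int(round(spec.lesion_area_mm2 / spec.spacing_mm ** 2))
        radius = np.sqrt(n_px / np.pi)
        # center on the horizontal midline at the gray-white interface, nudged
        # outward so ~90% of the disk lies in gray matter
        offset = _WHITE_CORE_RATIO * b_col + 0.7 * radius
        if offset + radius > 0.95 * b_col:
            raise ParameterError(
                f"lesion of {n_px} px does not fit the {spec.lesion_side} hemisphere")
        sign = -1.0 if spec.lesion_side == "left" else 1.0
        lesion = _lesion_disk((n, n), (center[0], center[1] + sign * offset), n_px)
        hu[lesion] = spec.lesion_hu

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)

    truth = PhantomTruth(brain_mask=brain, skull_mask=skull, lesion_mask=lesion,
                         lesion_side=spec.lesion_side)
    return CTSlice(hu, spacing_mm=spec.spacing_mm, source="phantom"), truth


def write_phantom_png(ct: CTSlice, path) -> None:
    """Store the HU slice as 16-bit PNG with a +1024 offset (lossy below -1024)."""
    import imageio.v3 as iio
    stored = np.clip(np.round(ct.pixels) + 1024, 0, 65535).astype(np.uint16)
    iio.imwrite(str(path), stored)


def write_phantom_dicom(ct: CTSlice, path) -> None:
    """Store the slice as a minimal synthetic single-frame CT DICOM."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = ct.pixels.shape
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.SamplesPerPixel = 1
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.PixelSpacing = [ct.spacing_mm, ct.spacing_mm]
    stored = np.clip(np.round(ct.pixels) + 1024, 0, 65535).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
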