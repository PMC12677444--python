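"""Calibrated CT volumes, 2-D images, and their DICOM/PNG round-trips.

Conventions used throughout the package:

* Volumes are indexed ``intensities[ix, iy, iz]`` with +x patient-left,
  +y anterior, +z cranial.  ``spacing_mm`` is ``(dx, dy, dz)`` and
  ``origin_mm`` is the world position of voxel ``(0, 0, 0)``.
* Intensities are Hounsfield units (HU): air -1000, water 0, cortical
  bone roughly 700-1200, enamel and metal well above 1500.
* 2-D images store pixels row-major with row 0 at the top (cranial end
  for panoramic views); ``resolution_mm_per_pixel`` is ``(row, col)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

AIR_HU = -1000.0

__all__ = [
    "AIR_HU",
    "VoxelVolume",
    "Image2D",
    "hu_threshold",
    "to_uint8",
    "read_series",
    "write_series",
    "write_image_8bit",
    "read_image",
]


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D HU grid with anisotropic physical spacing."""

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"intensities must be 3-D, got ndim={arr.ndim}")
        if any(n < 2 for n in arr.shape):
            raise ValueError(f"degenerate volume shape {arr.shape}; need >=2 voxels per axis")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive lengths, got {self.spacing_mm}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.shape[axis])

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (..., 3) to fractional voxel indices."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


@dataclass(frozen=True)
class Image2D:
    """A 2-D image with known physical resolution."""

    pixels: np.ndarray
    resolution_mm_per_pixel: tuple[float, float]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={arr.ndim}")
        res = tuple(float(r) for r in self.resolution_mm_per_pixel)
        if len(res) != 2 or any(r <= 0 for r in res):
            raise ValueError(f"resolution must be two positive lengths, got {res}")
        if arr.dtype.kind not in "fui":
            raise ValueError(f"unsupported pixel dtype {arr.dtype}")
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "resolution_mm_per_pixel", res)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def physical_size_mm(self) -> tuple[float, float]:
        """(height, width) covered by the pixel grid."""
        return (
            self.shape[0] * self.resolution_mm_per_pixel[0],
            self.shape[1] * self.resolution_mm_per_pixel[1],
        )


def hu_threshold(volume: VoxelVolume, cutoff_hu: float) -> np.ndarray:
    """Binary mask of voxels strictly above ``cutoff_hu``.

    This is the high-pass binarization used both for arch localization
    (500 HU, bones and teeth) and occlusal-plane estimation (3000 HU,
    teeth and restorations only).
    """
    if not np.isfinite(cutoff_hu):
        raise ValueError("cutoff_hu must be finite")
    return volume.intensities > cutoff_hu


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 255] with round-half-up.

    A constant image maps to all zeros; the choice is arbitrary and
    documented here rather than raising.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# DICOM series I/O


def write_series(volume: VoxelVolume, directory: str | Path, series_uid: str | None = None) -> None:
    """Write one CT DICOM file per axial slice.

    Stored values are ``HU + 1024`` with RescaleSlope 1 / RescaleIntercept
    -1024 so readers exercise the HU calibration path.  PixelSpacing,
    SpacingBetweenSlices and ImagePositionPatient are populated from the
    volume geometry.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    dx, dy, dz = volume.spacing_mm
    x0, y0, z0 = volume.origin_mm
    nx, ny, nz = volume.shape
    stored = np.clip(np.rint(volume.intensities) + 1024, -32768, 32767).astype(np.int16)
    for iz in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = iz + 1
        ds.ImagePositionPatient = [f"{x0:.6f}", f"{y0:.6f}", f"{z0 + iz * dz:.6f}"]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [f"{dy:.6f}", f"{dx:.6f}"]  # row spacing, column spacing
        ds.SliceThickness = f"{dz:.6f}"
        ds.SpacingBetweenSlices = f"{dz:.6f}"
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "-1024"
        ds.PixelData = np.ascontiguousarray(stored[:, :, iz].T).tobytes()
        ds.save_as(directory / f"slice_{iz:04d}.dcm", enforce_file_format=True)


def read_series(directory: str | Path) -> VoxelVolume:
    """Read a single-series DICOM slice stack into a calibrated volume.

    Slices are ordered by the z component of ImagePositionPatient (not by
    file name), HU calibration ``stored * slope + intercept`` is applied,
    and spacing is taken from the headers with the slice spacing measured
    as the inter-slice distance.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in {".dcm", ".ima", ""} and p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:
            continue
    if len(datasets) < 2:
        raise ValueError(f"need at least 2 slices of one series in {directory}, found {len(datasets)}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"mixed series in {directory}: {sorted(uids)}")
    for ds in datasets:
        if "PixelSpacing" not in ds or "ImagePositionPatient" not in ds:
            raise ValueError("slice missing PixelSpacing or ImagePositionPatient")
    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise ValueError(f"inconsistent pixel spacing across slices: {sorted(spacings)}")
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    dzs = np.diff(zs)
    if np.any(dzs <= 0):
        raise ValueError("duplicate or non-increasing slice positions")
    dz = float(np.median(dzs))
    dy, dx = next(iter(spacings))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    stack = np.stack(slices, axis=-1)  # (rows=y, cols=x, z)
    intensities = np.ascontiguousarray(np.transpose(stack, (1, 0, 2)))
    first = datasets[0]
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[2]),
    )
    return VoxelVolume(intensities, (dx, dy, dz), origin)


# ---------------------------------------------------------------------------
# 2-D image I/O


def write_image_8bit(image: Image2D, path: str | Path) -> None:
    """Write an image as 8-bit DICOM (default) or PNG with a resolution sidecar.

    Pixels are min-max rescaled to [0, 255] (already-uint8 input is kept
    verbatim) and the physical resolution is recorded: in PixelSpacing for
    DICOM, in a ``<path>.json`` sidecar for PNG.
    """
    path = Path(path)
    arr = image.pixels if image.pixels.dtype == np.uint8 else to_uint8(image.pixels)
    if path.suffix.lower() == ".png":
        from PIL import Image as PILImage

        PILImage.fromarray(arr, mode="L").save(path)
        sidecar = {"resolution_mm_per_pixel": list(image.resolution_mm_per_pixel)}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
        return
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.Rows, ds.Columns = arr.shape
    ds.PixelSpacing = [f"{image.resolution_mm_per_pixel[0]:.6f}", f"{image.resolution_mm_per_pixel[1]:.6f}"]
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(arr).tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_image(path: str | Path) -> Image2D:
    """Read an 8-bit DICOM or PNG (+sidecar) image written by this package."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image as PILImage

        arr = np.asarray(PILImage.open(path).convert("L"))
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise ValueError(f"missing resolution sidecar {sidecar}")
        res = json.loads(sidecar.read_text())["resolution_mm_per_pixel"]
        return Image2D(arr, (res[0], res[1]))
    ds = pydicom.dcmread(path)
    res = tuple(float(v) for v in ds.PixelSpacing)
    return Image2D(ds.pixel_array, res)
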