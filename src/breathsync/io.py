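"""Image containers and file I/O.

All downstream processing assumes one canonical in-memory geometry, fixed
here and never re-permuted later:

* planar images: axis 0 = superior -> inferior (rows), axis 1 = columns;
* volumes: axis 0 = superior -> inferior, axis 1 = anterior -> posterior,
  axis 2 = patient left -> right.

With this convention "the rows below the baseline X" is simply a slice
range on axis 0, for planars and volumes alike.

Two on-disk formats are supported: NIfTI (research/phantom data, written
and read losslessly through nibabel) and DICOM (clinical nuclear-medicine
objects, read-only through pydicom).  Pixel spacing is always taken from
file metadata; it is never guessed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pydicom

logger = logging.getLogger("breathsync")

#: Valid planar view labels.
VIEWS = ("anterior", "posterior")
#: Valid breathing-phase labels.
PHASES = ("deep_intake", "free_breathing")


class BreathSyncError(Exception):
    """Base class for all package errors."""


class ValidationError(BreathSyncError, ValueError):
    """Input violates a documented precondition."""


class ReadError(BreathSyncError, IOError):
    """File missing, truncated, or not in a recognized format."""


def _check_spacing(spacing: Sequence[float], ndim: int) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != ndim:
        raise ValidationError(f"expected {ndim} spacing values, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"pixel spacing must be strictly positive, got {spacing}")
    return spacing


def _check_counts(arr: np.ndarray, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError(f"{name} has zero size")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise ValidationError(f"{name} contains negative counts")
    return arr


@dataclass(frozen=True)
class PlanarImage:
    """A single 2-D gamma-camera acquisition.

    Counts are stored as floats even though acquisition is integer, because
    resampling during alignment and scaling produces non-integer values.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    view: str
    phase: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _check_counts(self.pixels, 2, "planar pixels"))
        object.__setattr__(
            self, "pixel_spacing_mm", _check_spacing(self.pixel_spacing_mm, 2)
        )
        if self.view not in VIEWS:
            raise ValidationError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SpectVolume:
    """Reconstructed 3-D count volume in the canonical axis order."""

    voxels: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", _check_counts(self.voxels, 3, "SPECT voxels"))
        object.__setattr__(
            self, "voxel_spacing_mm", _check_spacing(self.voxel_spacing_mm, 3)
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0


@dataclass(frozen=True)
class CtVolume:
    """CT volume on a Hounsfield-unit-like scale (signed intensities)."""

    voxels: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.ndim != 3:
            raise ValidationError(f"CT must be 3-D, got shape {arr.shape}")
        if arr.size == 0:
            raise ValidationError("CT has zero size")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("CT contains non-finite values")
        object.__setattr__(self, "voxels", arr)
        object.__setattr__(
            self, "voxel_spacing_mm", _check_spacing(self.voxel_spacing_mm, 3)
        )

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0


# ---------------------------------------------------------------------------
# NIfTI round-trip (phantoms, tests)
# ---------------------------------------------------------------------------

def _nifti_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing):
        aff[i, i] = s
    return aff


def _load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, ...]]:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise ReadError(f"cannot read {path}: {exc}") from exc
    zooms = img.header.get_zooms()[: data.ndim]
    if len(zooms) < data.ndim or any(z <= 0 for z in zooms):
        raise ReadError(f"{path}: missing or invalid pixel-spacing (pixdim) metadata")
    return data, tuple(float(z) for z in zooms)


# ---------------------------------------------------------------------------
# DICOM readers (clinical inputs; read-only)
# ---------------------------------------------------------------------------

def _load_dicom(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, ...]]:
    try:
        ds = pydicom.dcmread(str(path))
        data = ds.pixel_array.astype(np.float64)
    except Exception as exc:
        raise ReadError(f"cannot read {path}: {exc}") from exc
    if hasattr(ds, "RescaleSlope") or hasattr(ds, "RescaleIntercept"):
        data = data * float(getattr(ds, "RescaleSlope", 1.0)) + float(
            getattr(ds, "RescaleIntercept", 0.0)
        )
    spacing_rc = getattr(ds, "PixelSpacing", None)
    if spacing_rc is None:
        raise ReadError(f"{path}: DICOM object has no PixelSpacing attribute")
    spacing_rc = (float(spacing_rc[0]), float(spacing_rc[1]))
    if data.ndim == 2:
        return data, spacing_rc
    if data.ndim == 3:
        dz = getattr(ds, "SpacingBetweenSlices", None) or getattr(
            ds, "SliceThickness", None
        )
        if dz is None:
            raise ReadError(
                f"{path}: multi-frame DICOM lacks SpacingBetweenSlices/SliceThickness"
            )
        # pydicom yields (frame, row, col); frames stack along the axial axis,
        # rows already run superior->inferior in an NM coronal frame set, so
        # reorder frames to the canonical (SI, AP, LR) order.
        return np.transpose(data, (1, 0, 2)), (spacing_rc[0], float(dz), spacing_rc[1])
    raise ReadError(f"{path}: unsupported DICOM pixel data with ndim={data.ndim}")


def _is_dicom(path: str | os.PathLike) -> bool:
    p = str(path)
    if p.endswith((".dcm", ".DCM", ".ima")):
        return True
    try:
        with open(p, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_planar(path: str | os.PathLike, view: str, phase: str) -> PlanarImage:
    """Read a planar image from DICOM or NIfTI.

    ``view`` and ``phase`` are caller-supplied labels.  If the file carries a
    conflicting view tag (DICOM ``ViewPosition``) a warning is logged and the
    requested label wins: acquisition consoles are routinely mislabelled and
    the caller's study description is the authority.
    """
    if view not in VIEWS:
        raise ValidationError(f"view must be one of {VIEWS}, got {view!r}")
    if phase not in PHASES:
        raise ValidationError(f"phase must be one of {PHASES}, got {phase!r}")
    if not os.path.exists(path):
        raise ReadError(f"no such file: {path}")
    if _is_dicom(path):
        data, spacing = _load_dicom(path)
        ds = pydicom.dcmread(str(path), stop_before_pixels=True)
        stored = str(getattr(ds, "ViewPosition", "") or "").lower()
        tag_map = {"ant": "anterior", "post": "posterior"}
        if stored in tag_map and tag_map[stored] != view:
            logger.warning(
                "%s: stored view %r conflicts with requested %r; using requested",
                path, tag_map[stored], view,
            )
    else:
        data, spacing = _load_nifti(path)
    if data.ndim != 2:
        raise ReadError(f"{path}: planar image must be 2-D, got shape {data.shape}")
    if np.any(data < 0):
        raise ValidationError(f"{path}: planar image contains negative pixel values")
    return PlanarImage(data, (spacing[0], spacing[1]), view=view, phase=phase)


def write_planar(
    image: PlanarImage, path: str | os.PathLike, *, overwrite: bool = False
) -> Path:
    """Write a planar image as 2-D NIfTI, readable back by :func:`read_planar`."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise ValidationError(f"{path} exists; pass overwrite=True to replace it")
    img = nib.Nifti1Image(image.pixels, _nifti_affine(image.pixel_spacing_mm))
    img.header.set_zooms(image.pixel_spacing_mm)
    nib.save(img, str(path))
    return path


def read_spect(path: str | os.PathLike) -> SpectVolume:
    """Read a SPECT volume into the canonical axis convention.

    DICOM multi-frame objects are permuted from their stored frame order
    using header metadata; NIfTI volumes written by this package are already
    canonical, and foreign NIfTI volumes are assumed canonical (logged).
    """
    if not os.path.exists(path):
        raise ReadError(f"no such file: {path}")
    if _is_dicom(path):
        data, spacing = _load_dicom(path)
    else:
        data, spacing = _load_nifti(path)
        logger.info("%s: NIfTI volume assumed already in canonical (SI, AP, LR) order", path)
    if data.ndim != 3:
        raise ReadError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return SpectVolume(data, tuple(spacing))  # type: ignore[arg-type]


def read_ct(path: str | os.PathLike) -> CtVolume:
    """Read a CT volume (HU-like scale); same axis convention as SPECT."""
    if not os.path.exists(path):
        raise ReadError(f"no such file: {path}")
    if _is_dicom(path):
        data, spacing = _load_dicom(path)
    else:
        data, spacing = _load_nifti(path)
    if data.ndim != 3:
        raise ReadError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return CtVolume(data, tuple(spacing))  # type: ignore[arg-type]


def write_volume(
    volume: SpectVolume | CtVolume, path: str | os.PathLike, *, overwrite: bool = False
) -> Path:
    """Write a volume as NIfTI; ``read_spect(write_volume(v)) == v`` bitwise."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise ValidationError(f"{path} exists; pass overwrite=True to replace it")
    if volume.voxels.size == 0:
        raise ValidationError("refusing to write a zero-size volume")
    img = nib.Nifti1Image(volume.voxels, _nifti_affine(volume.voxel_spacing_mm))
    img.header.set_zooms(volume.voxel_spacing_mm)
    nib.save(img, str(path))
    return path
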