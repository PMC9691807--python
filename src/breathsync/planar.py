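"""Planar preparation: conjugate-view summation and rigid alignment.

The synchronization pipeline starts from four planar acquisitions
(anterior + posterior at deep intake and at free breathing) and the
reconstructed SPECT volume.  This module produces, per breathing phase,
a single planar image on the SPECT coronal grid:

1. the posterior view is mirrored left-right into the anterior frame and
   the two views are summed pixelwise (conjugate-view convention);
2. a coronal reference image is built from the SPECT volume as the full
   anterior->posterior sum projection -- the projection, not a single
   slice, because it matches the physics of a planar acquisition;
3. the summed deep-intake planar is resampled to the reference grid and
   rigidly aligned to it (in-plane translation + rotation) by minimizing
   mean squared error between total-count-normalized images; the free-
   breathing planar is then resampled and transformed with the *same*
   parameters, so the two phases stay mutually registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage, optimize

from .io import CtVolume, PlanarImage, SpectVolume, ValidationError


@dataclass(frozen=True)
class SummedPlanar:
    """Conjugate-view sum of an anterior/posterior pair for one phase."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    phase: str
    provenance: tuple[str, str] = ("anterior", "posterior")


@dataclass(frozen=True)
class CoronalReference:
    """SPECT coronal sum projection defining the target grid."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid transform: translation in mm plus rotation in degrees.

    The transform maps moving-image coordinates onto the reference grid;
    ``theta_deg`` is constrained to (-180, 180].
    """

    tx_mm: float
    ty_mm: float
    theta_deg: float

    def __post_init__(self) -> None:
        theta = ((self.theta_deg + 180.0) % 360.0) - 180.0
        if theta == -180.0:
            theta = 180.0
        object.__setattr__(self, "theta_deg", float(theta))


@dataclass(frozen=True)
class AlignedPlanar:
    """Summed planar resampled to the SPECT coronal grid and rigidly aligned."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    phase: str
    transform: RigidTransform2D


@dataclass
class RegistrationConfig:
    multistart_grid_px: tuple[int, ...] = (-8, -4, 0, 4, 8)
    max_iterations: int = 200
    tolerance: float = 1e-6


class RegistrationError(ValidationError):
    """Optimizer failed; carries the last iterate and the cost trace."""

    def __init__(self, message: str, last_iterate, cost_trace):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.cost_trace = cost_trace


def sum_planar_pair(anterior: PlanarImage, posterior: PlanarImage,
                    *, mirror_posterior: bool = True,
                    mode: str = "sum") -> SummedPlanar:
    """Sum an anterior/posterior pair into one planar image.

    The posterior view is mirrored left-right before summation so both views
    share the anterior anatomical frame.  ``mode='geometric_mean'`` computes
    the conjugate-view geometric mean instead of the arithmetic sum.
    """
    if anterior.view != "anterior" or posterior.view != "posterior":
        raise ValidationError(
            f"expected (anterior, posterior) views, got "
            f"({anterior.view!r}, {posterior.view!r})"
        )
    if anterior.phase != posterior.phase:
        raise ValidationError(
            f"phase mismatch: {anterior.phase!r} vs {posterior.phase!r}"
        )
    if anterior.shape != posterior.shape:
        raise ValidationError(
            f"shape mismatch: {anterior.shape} vs {posterior.shape}"
        )
    if anterior.pixel_spacing_mm != posterior.pixel_spacing_mm:
        raise ValidationError("pixel spacing mismatch between views")
    post = posterior.pixels[:, ::-1] if mirror_posterior else posterior.pixels
    if mode == "sum":
        combined = anterior.pixels + post
    elif mode == "geometric_mean":
        combined = np.sqrt(anterior.pixels * post)
    else:
        raise ValidationError(f"unknown summation mode {mode!r}")
    return SummedPlanar(combined, anterior.pixel_spacing_mm, anterior.phase)


def coronal_reference(spect: SpectVolume) -> CoronalReference:
    """Coronal reference image: sum projection along the anterior->posterior axis."""
    proj = spect.voxels.sum(axis=1)
    return CoronalReference(
        proj, (spect.voxel_spacing_mm[0], spect.voxel_spacing_mm[2])
    )


def _resample_to_grid(pixels: np.ndarray, spacing: tuple[float, float],
                      target_shape: tuple[int, int],
                      target_spacing: tuple[float, float]) -> np.ndarray:
    """Pure scaling resample from one (spacing, matrix) onto another.

    Image centers are kept coincident; linear interpolation, zero fill.
    """
    if pixels.shape == target_shape and spacing == target_spacing:
        return pixels.astype(np.float64, copy=True)
    rows = np.arange(target_shape[0], dtype=np.float64)
    cols = np.arange(target_shape[1], dtype=np.float64)
    src_r = (rows - (target_shape[0] - 1) / 2) * target_spacing[0] / spacing[0] \
        + (pixels.shape[0] - 1) / 2
    src_c = (cols - (target_shape[1] - 1) / 2) * target_spacing[1] / spacing[1] \
        + (pixels.shape[1] - 1) / 2
    rr, cc = np.meshgrid(src_r, src_c, indexing="ij")
    return ndimage.map_coordinates(
        np.asarray(pixels, dtype=np.float64), [rr, cc], order=1, cval=0.0
    )


def _apply_rigid(pixels: np.ndarray, tx_px: float, ty_px: float,
                 theta_deg: float) -> np.ndarray:
    """Apply a rigid transform about the image center (linear interp, zero fill)."""
    theta = np.deg2rad(theta_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    center = (np.asarray(pixels.shape, dtype=np.float64) - 1) / 2
    # inverse mapping: output coordinate -> input coordinate, rotation about
    # the image center, translation (tx=cols, ty=rows) applied after rotation
    offset = center - rot.T @ center - rot.T @ np.array([ty_px, tx_px])
    return ndimage.affine_transform(
        np.asarray(pixels, dtype=np.float64), rot.T, offset=offset,
        order=1, cval=0.0,
    )


def _normalize(img: np.ndarray) -> np.ndarray:
    total = img.sum()
    if total <= 0:
        raise ValidationError("cannot normalize an all-zero image")
    return img / total


def align_planar_to_reference(
    planar: SummedPlanar,
    reference: CoronalReference,
    config: RegistrationConfig | None = None,
    transform: RigidTransform2D | None = None,
) -> AlignedPlanar:
    """Resample a summed planar to the reference grid and rigidly align it.

    Both images are scaled to unit total counts before the mean-squared-error
    cost is evaluated, since planar and projected-SPECT count scales differ by
    acquisition duration.  Optimization is a coarse multi-start over integer
    translations followed by Powell refinement of (tx, ty, theta).

    Passing ``transform`` skips optimization and applies the given transform
    (used for the free-breathing image, which reuses the deep-intake result).
    """
    config = config or RegistrationConfig()
    resampled = _resample_to_grid(
        planar.pixels, planar.pixel_spacing_mm,
        reference.pixels.shape, reference.pixel_spacing_mm,
    )
    sp = reference.pixel_spacing_mm
    if transform is not None:
        moved = _apply_rigid(
            resampled, transform.tx_mm / sp[1], transform.ty_mm / sp[0],
            transform.theta_deg,
        )
        return AlignedPlanar(moved, sp, planar.phase, transform)

    ref_n = _normalize(np.asarray(reference.pixels, dtype=np.float64))
    mov_n = _normalize(resampled)

    cost_trace: list[float] = []

    def cost(params: np.ndarray) -> float:
        tx, ty, theta = params
        moved = _apply_rigid(mov_n, tx, ty, theta)
        c = float(np.mean((moved - ref_n) ** 2))
        cost_trace.append(c)
        return c

    # multi-start: coarse integer-translation grid at zero rotation
    best0 = np.zeros(3)
    best_cost = cost(best0)
    for dx in config.multistart_grid_px:
        for dy in config.multistart_grid_px:
            if dx == 0 and dy == 0:
                continue
            c = cost(np.array([dx, dy, 0.0]))
            if c < best_cost:
                best_cost, best0 = c, np.array([dx, dy, 0.0], dtype=float)

    res = optimize.minimize(
        cost, best0, method="Powell",
        options={"maxiter": config.max_iterations,
                 "xtol": config.tolerance, "ftol": config.tolerance},
    )
    if not (res.success or res.fun <= best_cost + 1e-15):
        raise RegistrationError(
            f"rigid registration did not converge: {res.message}",
            last_iterate=res.x, cost_trace=cost_trace,
        )
    params = res.x if res.fun <= best_cost else best0
    tx_px, ty_px, theta = float(params[0]), float(params[1]), float(params[2])
    moved = _apply_rigid(resampled, tx_px, ty_px, theta)
    tf = RigidTransform2D(tx_mm=tx_px * sp[1], ty_mm=ty_px * sp[0], theta_deg=theta)
    return AlignedPlanar(moved, sp, planar.phase, tf)
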