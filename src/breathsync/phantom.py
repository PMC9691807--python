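"""Digital breathing phantoms with known ground truth.

Each phantom is a pair of breathing states of the same two-lung activity
distribution on a 128-cube grid at SPECT resolution:

* the *deep-intake* state is the reference anatomy: two ellipsoidal lungs
  of uniform tracer activity (plus a matching CT with air-like lung HU);
* the *free-breathing* state is derived from it by the exact inverse of
  the correction model -- rows below the true baseline ``X*`` compressed
  by ``1/Y*`` -- so that recovering ``(X*, Y*)`` is a well-posed task;
* both states are smoothed with an isotropic Gaussian (a point-spread
  surrogate for collimator + reconstruction blur) and projected into
  anterior/posterior planars; Poisson count noise is optional.

Compression is applied to the sharp activity before blurring, mirroring
reality: the anatomy deforms, then the imaging system blurs it.

True lung volumes are computed analytically from the ellipsoid parameters
(the free-breathing volume uses the ellipsoid-cap integral for the portion
below the baseline, which the compression divides by ``Y*``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import CtVolume, PlanarImage, SpectVolume, ValidationError
from .sync import ScalingParams, deform_spect


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, counts and ground-truth deformation of one synthetic case.

    Lengths are millimetres in the canonical axes (origin at voxel 0);
    ``true_X`` is a row index.  Defaults give a ~3.8 L deep-inspiration
    lung pair on a 128-cube 4.42 mm grid, planar peak counts near 500,
    and a 6 mm point-spread sigma.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing_mm: tuple[float, float, float] = (4.42, 4.42, 4.42)
    lung_centers_mm: tuple[tuple[float, float, float], ...] = (
        (252.0, 283.0, 208.0),
        (252.0, 283.0, 358.0),
    )
    lung_semi_axes_mm: tuple[float, float, float] = (125.0, 75.0, 48.0)
    activity: float = 500.0
    activity_profile: str = "parabolic"  # or "uniform"
    blur_sigma_mm: float = 6.0
    true_X: int = 45
    true_Y: float = 1.2
    noise: str = "none"
    seed: int = 0
    lateral_drift_mm: float = 0.0  # model-mismatch mode: free-state LR shift

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValidationError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        if self.activity_profile not in ("parabolic", "uniform"):
            raise ValidationError(
                f"activity_profile must be 'parabolic' or 'uniform', "
                f"got {self.activity_profile!r}"
            )
        if not (self.true_Y > 0):
            raise ValidationError(f"true_Y must be positive, got {self.true_Y}")
        if not (0 <= self.true_X < self.shape[0]):
            raise ValidationError(f"true_X={self.true_X} outside axis-0 extent")


@dataclass(frozen=True)
class PhantomTruth:
    true_X: int
    true_Y: float
    lung_volume_ml_deep: float
    lung_volume_ml_free: float


@dataclass(frozen=True)
class PhantomCase:
    spec: PhantomSpec
    spect_deep_truth: SpectVolume
    spect_free: SpectVolume
    planars: dict  # keys (phase, view) -> PlanarImage
    ct: CtVolume
    truth: PhantomTruth


def _ellipsoid_r2(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return sum(
        ((g * sp - c) / a) ** 2
        for g, sp, c, a in zip(grids, spacing, center_mm, semi_mm)
    )


def _ellipsoid_mask(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    return _ellipsoid_r2(shape, spacing, center_mm, semi_mm) <= 1.0


def _cap_volume_below_ml(center0_mm, semi_mm, plane_mm) -> float:
    """Volume (ml) of the ellipsoid part on the inferior side of a plane."""
    a, b, c = semi_mm
    t0 = np.clip((plane_mm - center0_mm) / a, -1.0, 1.0)
    return math.pi * a * b * c * (2.0 / 3.0 - t0 + t0**3 / 3.0) / 1000.0


def analytic_lung_volumes(spec: PhantomSpec) -> tuple[float, float]:
    """(deep, free) total lung volumes in ml from the ellipsoid parameters."""
    a, b, c = spec.lung_semi_axes_mm
    v_one = 4.0 / 3.0 * math.pi * a * b * c / 1000.0
    plane_mm = spec.true_X * spec.voxel_spacing_mm[0]
    v_deep = 0.0
    v_free = 0.0
    for center in spec.lung_centers_mm:
        below = _cap_volume_below_ml(center[0], spec.lung_semi_axes_mm, plane_mm)
        v_deep += v_one
        v_free += (v_one - below) + below / spec.true_Y
    return v_deep, v_free


def _check_geometry(spec: PhantomSpec) -> None:
    extent_mm = [s * n for s, n in zip(spec.voxel_spacing_mm, spec.shape)]
    for center in spec.lung_centers_mm:
        for ax in range(3):
            lo = center[ax] - spec.lung_semi_axes_mm[ax]
            hi = center[ax] + spec.lung_semi_axes_mm[ax]
            if lo < 0 or hi > extent_mm[ax]:
                raise ValidationError(
                    f"lung ellipsoid at {center} exceeds matrix extent on axis {ax}"
                )
    if spec.true_Y < 1.0:
        # compression by 1/Y > 1 pushes the caudal edge down; check it fits
        plane = spec.true_X * spec.voxel_spacing_mm[0]
        for center in spec.lung_centers_mm:
            base = center[0] + spec.lung_semi_axes_mm[0]
            new_base = plane + (base - plane) / spec.true_Y
            if new_base > extent_mm[0]:
                raise ValidationError(
                    "free-breathing geometry overflows the matrix after deformation"
                )


def project_planar(
    volume: SpectVolume, view: str, phase: str = "free_breathing"
) -> PlanarImage:
    """Forward-project a volume into a planar view.

    Sum projection along the anterior->posterior axis; the posterior view is
    the left-right mirror of the anterior one (the camera sees the patient
    from behind).  Total counts are preserved.
    """
    if view not in ("anterior", "posterior"):
        raise ValidationError(f"unknown view {view!r}")
    proj = volume.voxels.sum(axis=1)
    if view == "posterior":
        proj = proj[:, ::-1]
    return PlanarImage(
        proj,
        (volume.voxel_spacing_mm[0], volume.voxel_spacing_mm[2]),
        view=view,
        phase=phase,
    )


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build one phantom case; deterministic given ``spec.seed``."""
    _check_geometry(spec)
    sp = spec.voxel_spacing_mm

    # perfusion tracer uptake peaks centrally and fades toward the pleural
    # surface; the parabolic profile (1 - r^2) emulates that, which is what
    # makes percent-of-maximum thresholds cut at (not outside) the lung edge
    act_deep = np.zeros(spec.shape)
    for center in spec.lung_centers_mm:
        r2 = _ellipsoid_r2(spec.shape, sp, center, spec.lung_semi_axes_mm)
        inside = r2 <= 1.0
        if spec.activity_profile == "parabolic":
            act_deep[inside] = np.maximum(act_deep[inside], (1.0 - r2)[inside])
        else:
            act_deep[inside] = 1.0
    if not act_deep.any():
        raise ValidationError("phantom activity is empty")

    # free breathing = inverse of the correction model applied to the sharp
    # deep-intake activity (compress rows below X by 1/Y), then blur
    inv = ScalingParams(spec.true_X, 1.0 / spec.true_Y)
    act_free = deform_spect(SpectVolume(act_deep, sp), inv).voxels
    if spec.lateral_drift_mm != 0.0:
        act_free = ndimage.shift(
            act_free, (0.0, 0.0, spec.lateral_drift_mm / sp[2]), order=1, cval=0.0
        )

    sigma_vox = [spec.blur_sigma_mm / s for s in sp]
    b_deep = ndimage.gaussian_filter(act_deep, sigma_vox) if spec.blur_sigma_mm > 0 else act_deep
    b_free = ndimage.gaussian_filter(act_free, sigma_vox) if spec.blur_sigma_mm > 0 else act_free

    # count scales: volumes and planars are separate acquisitions; both are
    # normalized so the free-breathing maximum hits the configured activity
    vol_scale = spec.activity / b_free.max()
    deep_vol = b_deep * vol_scale
    free_vol = b_free * vol_scale

    proj_scale = spec.activity / b_free.sum(axis=1).max()
    planars: dict[tuple[str, str], PlanarImage] = {}
    for phase, vol in (("deep_intake", b_deep), ("free_breathing", b_free)):
        scaled = SpectVolume(vol * proj_scale, sp)
        for view in ("anterior", "posterior"):
            planars[(phase, view)] = project_planar(scaled, view, phase)

    if spec.noise == "poisson":
        seq = np.random.SeedSequence(spec.seed)
        sub = seq.spawn(len(planars) + 1)
        free_vol = np.random.default_rng(sub[0]).poisson(free_vol).astype(np.float64)
        for i, key in enumerate(sorted(planars)):
            p = planars[key]
            noisy = np.random.default_rng(sub[i + 1]).poisson(p.pixels)
            planars[key] = PlanarImage(
                noisy.astype(np.float64), p.pixel_spacing_mm, p.view, p.phase
            )

    ct = np.full(spec.shape, -1000.0)
    # thorax surrogate: elliptical cylinder along axis 0, fully enclosing the
    # lungs so that hole-filling recovers them inside the body mask
    g0, g1, g2 = np.ogrid[: spec.shape[0], : spec.shape[1], : spec.shape[2]]
    c1 = spec.shape[1] * sp[1] / 2
    c2 = spec.shape[2] * sp[2] / 2
    cross = ((g1 * sp[1] - c1) / 120.0) ** 2 + ((g2 * sp[2] - c2) / 180.0) ** 2 <= 1.0
    axial = (g0 >= 10) & (g0 <= spec.shape[0] - 10)
    ct[cross & axial] = 0.0
    for center in spec.lung_centers_mm:
        ct[_ellipsoid_mask(spec.shape, sp, center, spec.lung_semi_axes_mm)] = -800.0

    v_deep, v_free = analytic_lung_volumes(spec)
    return PhantomCase(
        spec=spec,
        spect_deep_truth=SpectVolume(deep_vol, sp),
        spect_free=SpectVolume(free_vol, sp),
        planars=planars,
        ct=CtVolume(ct, sp),
        truth=PhantomTruth(spec.true_X, spec.true_Y, v_deep, v_free),
    )
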