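"""Breathing synchronization: the two-parameter caudal scaling model.

Free-breathing SPECT is acquired with the diaphragm, on average, higher
than on a breath-hold deep-inspiration CT, so the caudal lung is displaced
and compressed relative to the CT.  The correction model is deliberately
minimal: a baseline row ``X`` (superior->inferior axis) above which nothing
moves, and a magnification ``Y`` applied to everything below it,

    r' = X + (r - X) * Y        for r >= X,  r' = r otherwise.

``(X, Y)`` are estimated in 2-D from the aligned planar images -- the
free-breathing planar is scaled and compared against the deep-intake planar
with normalized mutual information, NMI = (H(A) + H(B)) / H(A, B) -- and
then the same one-dimensional axis-0 remapping is applied to every
(depth, column) line of the SPECT volume.

The search is an exhaustive grid (integer X over a caudal band, Y on a
fixed step).  A 2-D bounded grid is cheap, fully reproducible, and immune
to the local maxima that make NMI surfaces hostile to gradient methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BreathSyncError, PlanarImage, SpectVolume, ValidationError
from .planar import (
    AlignedPlanar,
    RegistrationConfig,
    align_planar_to_reference,
    coronal_reference,
    sum_planar_pair,
)


@dataclass(frozen=True)
class ScalingParams:
    """Baseline row ``X`` (integer, axis 0) and magnification ``Y`` (> 0)."""

    X: int
    Y: float

    def __post_init__(self) -> None:
        if int(self.X) != self.X or self.X < 0:
            raise ValidationError(f"X must be a non-negative integer row, got {self.X}")
        object.__setattr__(self, "X", int(self.X))
        if not (self.Y > 0):
            raise ValidationError(f"Y must be positive, got {self.Y}")


@dataclass(frozen=True)
class NmiValue:
    """Normalized mutual information with the bin count used to compute it."""

    value: float
    bins: int


@dataclass
class SearchConfig:
    """Grid-search space for (X, Y).

    Defaults cover the caudal half of a 128-row matrix and magnifications
    from 0.8 to 1.6 in steps of 0.01 -- generous for diaphragm excursion.
    """

    x_min: int = 30
    x_max: int = 100
    y_min: float = 0.8
    y_max: float = 1.6
    y_step: float = 0.01
    bins: int = 64

    def x_values(self) -> np.ndarray:
        return np.arange(self.x_min, self.x_max + 1)

    def y_values(self) -> np.ndarray:
        n = int(round((self.y_max - self.y_min) / self.y_step)) + 1
        return np.round(self.y_min + self.y_step * np.arange(n), 10)


@dataclass
class SyncConfig:
    """End-to-end pipeline settings."""

    mirror_posterior: bool = True
    summation_mode: str = "sum"
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    search: SearchConfig = field(default_factory=SearchConfig)


@dataclass
class SyncResult:
    params: ScalingParams
    objective: NmiValue
    scaled_planar: np.ndarray
    scaled_spect: SpectVolume
    search_trace: list[tuple[int, float, float]]
    transform: object = None  # RigidTransform2D from the alignment stage


# ---------------------------------------------------------------------------
# Normalized mutual information
# ---------------------------------------------------------------------------

def _digitize(img: np.ndarray, bins: int) -> np.ndarray:
    lo = img.min()
    hi = img.max()
    if hi == lo:
        raise ValidationError(
            "constant image: joint entropy is degenerate, NMI undefined"
        )
    idx = ((img - lo) * (bins / (hi - lo))).astype(np.intp)
    np.clip(idx, 0, bins - 1, out=idx)
    return idx


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def normalized_mutual_information(
    img_a: np.ndarray, img_b: np.ndarray, bins: int = 64
) -> NmiValue:
    """NMI = (H(A) + H(B)) / H(A, B) from a joint intensity histogram.

    Each image is binned into ``bins`` equal-width bins spanning its own
    min-max range.  Lies in [1, 2] for non-constant images; 2 iff the images
    are related by a bin-level bijection.
    """
    img_a = np.asarray(img_a, dtype=np.float64)
    img_b = np.asarray(img_b, dtype=np.float64)
    if img_a.shape != img_b.shape:
        raise ValidationError(f"shape mismatch: {img_a.shape} vs {img_b.shape}")
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    ia = _digitize(img_a.ravel(), bins)
    ib = _digitize(img_b.ravel(), bins)
    return NmiValue(_nmi_from_digitized(ia, ib, bins), bins)


def _nmi_from_digitized(ia: np.ndarray, ib: np.ndarray, bins: int) -> float:
    joint = np.bincount(ia * bins + ib, minlength=bins * bins).astype(np.float64)
    joint /= joint.sum()
    pj = joint.reshape(bins, bins)
    h_a = _entropy(pj.sum(axis=1))
    h_b = _entropy(pj.sum(axis=0))
    h_ab = _entropy(joint)
    return (h_a + h_b) / h_ab


# ---------------------------------------------------------------------------
# Caudal scaling (1-D remap along the superior->inferior axis)
# ---------------------------------------------------------------------------

def _axis0_weights(
    height: int, params: ScalingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-mapping interpolation weights for the axis-0 remap.

    Output row r takes its value from source row X + (r - X)/Y (rows above X
    are fixed), split linearly between the two neighbouring integer rows.
    Rows whose source falls outside the image are zero-filled.
    """
    if not (0 <= params.X < height):
        raise ValidationError(
            f"baseline X={params.X} outside image height {height}"
        )
    rows = np.arange(height, dtype=np.float64)
    src = rows.copy()
    below = rows >= params.X
    src[below] = params.X + (rows[below] - params.X) / params.Y
    valid = (src >= 0) & (src <= height - 1)
    lo = np.floor(src).astype(np.intp)
    frac = src - lo
    lo = np.clip(lo, 0, height - 1)
    hi = np.minimum(lo + 1, height - 1)
    return lo, hi, frac, valid


def scale_below_baseline(img: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Stretch (Y > 1) or compress (Y < 1) the rows below baseline X.

    Content mapped past the bottom edge is cropped; rows with no source are
    zero-filled.  Output shape equals input shape.  Y = 1 returns a bitwise
    copy of the input.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got shape {img.shape}")
    if params.Y == 1.0:
        if not (0 <= params.X < img.shape[0]):
            raise ValidationError(
                f"baseline X={params.X} outside image height {img.shape[0]}"
            )
        return img.copy()
    lo, hi, frac, valid = _axis0_weights(img.shape[0], params)
    out = img[lo] * (1.0 - frac)[:, None] + img[hi] * frac[:, None]
    out[~valid] = 0.0
    return out


def deform_spect(spect: SpectVolume, params: ScalingParams) -> SpectVolume:
    """Apply the planar-estimated axis-0 remap to every line of the volume.

    Voxel intensities are interpolated, not Jacobian-rescaled: the end use is
    spatial conformity and thresholded volume, which count-conservation
    rescaling would distort.
    """
    if params.Y == 1.0:
        if not (0 <= params.X < spect.shape[0]):
            raise ValidationError(
                f"baseline X={params.X} outside volume extent {spect.shape[0]}"
            )
        return SpectVolume(spect.voxels.copy(), spect.voxel_spacing_mm)
    lo, hi, frac, valid = _axis0_weights(spect.shape[0], params)
    vox = spect.voxels
    out = vox[lo] * (1.0 - frac)[:, None, None] + vox[hi] * frac[:, None, None]
    out[~valid] = 0.0
    return SpectVolume(out, spect.voxel_spacing_mm)


# ---------------------------------------------------------------------------
# Parameter search
# ---------------------------------------------------------------------------

def optimize_scaling(
    img_c: AlignedPlanar | np.ndarray,
    img_d: AlignedPlanar | np.ndarray,
    search: SearchConfig | None = None,
) -> tuple[ScalingParams, list[tuple[int, float, float]]]:
    """Exhaustive grid search maximizing NMI(C, scale(D; X, Y)).

    Returns the global grid maximizer and the full (X, Y, NMI) trace.  Exact
    NMI ties are broken toward the least deformation: smallest ``|Y - 1|``,
    then smallest ``X``.
    """
    search = search or SearchConfig()
    c = img_c.pixels if isinstance(img_c, AlignedPlanar) else np.asarray(img_c, float)
    d = img_d.pixels if isinstance(img_d, AlignedPlanar) else np.asarray(img_d, float)
    if isinstance(img_c, AlignedPlanar) and img_c.phase != "deep_intake":
        raise ValidationError("img_c (reference) must be the deep-intake image")
    if isinstance(img_d, AlignedPlanar) and img_d.phase != "free_breathing":
        raise ValidationError("img_d (moving) must be the free-breathing image")
    if c.shape != d.shape:
        raise ValidationError(f"grid mismatch: {c.shape} vs {d.shape}")
    height = c.shape[0]
    xs = [int(x) for x in search.x_values() if 0 <= x < height]
    ys = search.y_values()
    if len(xs) == 0 or len(ys) == 0:
        raise ValidationError("empty (X, Y) search space")

    bins = search.bins
    ic = _digitize(c.ravel(), bins)  # reference binned once

    trace: list[tuple[int, float, float]] = []
    best: tuple[float, float, int] | None = None  # (-nmi, |Y-1|, X) lexicographic
    best_params: ScalingParams | None = None
    n_degenerate = 0
    for x in xs:
        for y in ys:
            params = ScalingParams(x, float(y))
            e = scale_below_baseline(d, params)
            lo_v, hi_v = e.min(), e.max()
            if hi_v == lo_v:
                n_degenerate += 1
                continue
            ie = ((e.ravel() - lo_v) * (bins / (hi_v - lo_v))).astype(np.intp)
            np.clip(ie, 0, bins - 1, out=ie)
            nmi = _nmi_from_digitized(ic, ie, bins)
            trace.append((x, float(y), nmi))
            key = (-nmi, abs(float(y) - 1.0), x)
            if best is None or key < best:
                best, best_params = key, params
    if best_params is None:
        raise ValidationError(
            f"all {n_degenerate} grid points degenerate (constant scaled image)"
        )
    return best_params, trace


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def synchronize(
    spect: SpectVolume,
    ant_deep: PlanarImage,
    post_deep: PlanarImage,
    ant_free: PlanarImage,
    post_free: PlanarImage,
    config: SyncConfig | None = None,
) -> SyncResult:
    """Run the four-step pipeline and return the deformed SPECT plus audit trail.

    1. sum conjugate views per phase; 2. build the coronal reference and
    rigidly align the deep-intake sum to it, reusing the same transform for
    the free-breathing sum; 3. grid-search (X, Y) maximizing NMI; 4. deform
    the SPECT volume with the winning parameters.
    """
    config = config or SyncConfig()

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except BreathSyncError as exc:
            exc.args = (f"[{name}] {exc.args[0] if exc.args else exc}",) + exc.args[1:]
            raise

    summed_deep = _stage(
        "step1-sum", sum_planar_pair, ant_deep, post_deep,
        mirror_posterior=config.mirror_posterior, mode=config.summation_mode,
    )
    summed_free = _stage(
        "step1-sum", sum_planar_pair, ant_free, post_free,
        mirror_posterior=config.mirror_posterior, mode=config.summation_mode,
    )
    reference = _stage("step2-reference", coronal_reference, spect)
    img_c = _stage(
        "step2-align", align_planar_to_reference,
        summed_deep, reference, config.registration,
    )
    img_d = _stage(
        "step2-align", align_planar_to_reference,
        summed_free, reference, config.registration, transform=img_c.transform,
    )
    params, trace = _stage("step3-search", optimize_scaling, img_c, img_d, config.search)
    scaled_planar = _stage("step3-scale", scale_below_baseline, img_d.pixels, params)
    objective = _stage(
        "step3-nmi", normalized_mutual_information,
        img_c.pixels, scaled_planar, config.search.bins,
    )
    scaled_spect = _stage("step4-deform", deform_spect, spect, params)
    return SyncResult(
        params=params,
        objective=objective,
        scaled_planar=scaled_planar,
        scaled_spect=scaled_spect,
        search_trace=trace,
        transform=img_c.transform,
    )
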