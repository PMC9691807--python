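"""Histogram-based lung volumetry from SPECT, plus a simple CT surrogate.

The lung edge on a perfusion SPECT has no anatomical boundary: it is
defined operationally as the set of voxels whose count is at least a fixed
fraction (the *cutoff level*) of the volume's maximum count.  The lung
volume is then the number of supra-threshold voxels times the voxel
volume -- equivalently, summing a count histogram's volume-per-count from
the threshold up to the maximum.  The cutoff is swept (typically 5-20% of
the maximum) rather than hard-coded, because the best level depends on
reconstruction blur.

The CT lung volume here is a deliberately simple surrogate for the
commercial-workstation segmentation used clinically: an air-like HU band
inside the body mask, largest connected components kept.  It is adequate
for phantom CTs with clean HU plateaus and makes no claim of equivalence
on clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CtVolume, SpectVolume, ValidationError


@dataclass(frozen=True)
class CountHistogram:
    """Histogram of voxel counts with the per-voxel volume attached."""

    bin_edges: np.ndarray
    voxels_per_bin: np.ndarray
    voxel_volume_ml: float


@dataclass(frozen=True)
class VolumeResult:
    cutoff_fraction: float
    threshold_count: float
    n_voxels: int
    volume_ml: float


def count_histogram(spect: SpectVolume, n_bins: int = 256) -> CountHistogram:
    """Histogram of the volume's voxel counts (all voxels accounted for)."""
    counts, edges = np.histogram(spect.voxels.ravel(), bins=n_bins)
    return CountHistogram(edges, counts, spect.voxel_volume_ml)


def threshold_count(max_count: float, cutoff_fraction: float) -> float:
    """Count level at a given fraction of the maximum (edge comparison is >=)."""
    if not (max_count > 0):
        raise ValidationError(f"max_count must be positive, got {max_count}")
    if not (0 < cutoff_fraction <= 1):
        raise ValidationError(
            f"cutoff_fraction must be in (0, 1], got {cutoff_fraction}"
        )
    return float(max_count) * float(cutoff_fraction)


def spect_lung_volume(
    spect: SpectVolume,
    cutoff_fraction: float,
    *,
    robust_max: bool = False,
    largest_components: int | None = None,
) -> VolumeResult:
    """Supra-threshold lung volume at one cutoff level.

    The maximum is the single maximum voxel count by default;
    ``robust_max=True`` uses the 99.9th percentile instead.  Voxels with
    counts >= threshold are lung (inclusive edge: the histogram sum runs
    from the threshold count up to the maximum).  ``largest_components``
    optionally keeps only the N largest connected supra-threshold
    components; the default applies no component filtering, matching a
    pure histogram sum.
    """
    vox = spect.voxels
    max_count = float(np.percentile(vox, 99.9)) if robust_max else float(vox.max())
    if max_count <= 0:
        raise ValidationError("volume has no positive voxel; cannot threshold")
    thr = threshold_count(max_count, cutoff_fraction)
    mask = vox >= thr
    if largest_components is not None:
        labels, n = ndimage.label(mask)
        if n > largest_components:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            keep = np.argsort(sizes)[::-1][:largest_components] + 1
            mask = np.isin(labels, keep)
    n_voxels = int(mask.sum())
    return VolumeResult(
        cutoff_fraction=float(cutoff_fraction),
        threshold_count=thr,
        n_voxels=n_voxels,
        volume_ml=n_voxels * spect.voxel_volume_ml,
    )


def sweep_cutoffs(
    spect: SpectVolume, cutoffs=(0.05, 0.10, 0.15, 0.20), **kwargs
) -> list[VolumeResult]:
    """Volumes over a cutoff sweep (volume is non-increasing in the cutoff)."""
    return [spect_lung_volume(spect, c, **kwargs) for c in cutoffs]


def ct_lung_volume(
    ct: CtVolume,
    *,
    air_low: float = -1000.0,
    air_high: float = -200.0,
    body_threshold: float = -500.0,
    n_components: int = 2,
) -> float:
    """Lung volume (ml) from a CT by HU-band segmentation inside the body.

    Voxels with HU in [air_low, air_high] that lie inside the body mask
    (body = HU > body_threshold, holes filled) are lung candidates; the
    ``n_components`` largest connected components are kept.
    """
    hu = ct.voxels
    body = ndimage.binary_fill_holes(hu > body_threshold)
    candidates = body & (hu >= air_low) & (hu <= air_high)
    labels, n = ndimage.label(candidates)
    if n == 0:
        raise ValidationError("empty CT lung segmentation (no voxels in HU band)")
    sizes = ndimage.sum_labels(candidates, labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][: min(n_components, n)] + 1
    n_voxels = int(np.isin(labels, keep).sum())
    if n_voxels == 0:
        raise ValidationError("empty CT lung segmentation")
    return n_voxels * ct.voxel_volume_ml
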