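"""Voxelwise single-case t-maps: the SPM-style baseline.

Each patient is compared voxel-by-voxel against the healthy control
group after normalization to a common space and 6 mm smoothing:

    t = (x - mbar) / (s * sqrt(1 + 1/n)),  df = n - 1

which is algebraically the pooled two-sample t with group sizes 1 and n.
Hypometabolism is a one-sided lower-tail question, so thresholding uses
the lower tail and a ladder: clusters of >= 20 voxels at p < 0.001,
falling back to p < 0.05, falling back to the single global-minimum-t
voxel.  The statistic map is finally resampled back to the patient's
native space through the inverse warp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .errors import GeometryError, ValidationError
from .phantom import WarpField
from .volumes import VolumeImage

log = logging.getLogger("cbmpet")

__all__ = [
    "TMap",
    "TMapSettings",
    "VoxelCluster",
    "normalize_to_group",
    "single_case_t",
    "threshold_tmap",
    "inverse_normalize",
]


@dataclass
class TMap:
    """Per-voxel single-case t-statistics.

    ``valid`` marks voxels with positive control SD; elsewhere t is set
    to 0 and excluded from thresholding.
    """

    t: np.ndarray
    df: int
    affine: np.ndarray
    space: str = "group"  # "group" | "native"
    valid: np.ndarray | None = None

    def as_volume(self) -> VolumeImage:
        return VolumeImage(self.t, self.affine)


@dataclass
class TMapSettings:
    smooth_fwhm_mm: float = 6.0
    p_primary: float = 0.001
    p_fallback: float = 0.05
    cluster_extent_k: int = 20
    connectivity: int = 18  # 6 | 18 | 26

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValidationError("connectivity must be 6, 18 or 26")
        if not 0.0 < self.p_primary <= self.p_fallback < 1.0:
            raise ValidationError("need 0 < p_primary <= p_fallback < 1")
        if self.cluster_extent_k < 1:
            raise ValidationError("cluster_extent_k must be >= 1")


@dataclass
class VoxelCluster:
    """A connectivity-linked set of suprathreshold voxels."""

    voxels: np.ndarray  # (m, 3) integer indices
    peak_voxel: tuple[int, int, int]
    peak_t: float
    mean_t: float

    def __len__(self) -> int:
        return len(self.voxels)


def normalize_to_group(volume: VolumeImage, warp: WarpField) -> VolumeImage:
    """Trilinear resampling through the forward warp onto the group grid."""
    return warp.apply(volume, inverse=False, order=1)


def single_case_t(patient: VolumeImage, controls: list[VolumeImage]) -> TMap:
    """Voxelwise one-vs-group t statistic with df = n_controls - 1.

    Voxels with zero control SD are excluded (t set to 0) and counted in
    the log.
    """
    n = len(controls)
    if n < 3:
        raise ValidationError(f"need >= 3 controls, got {n}")
    for c in controls:
        if c.shape != patient.shape:
            raise GeometryError("control grid does not match patient grid")
    stack = np.stack([c.data for c in controls])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    valid = sd > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        log.info("single_case_t: %d voxels with zero control SD excluded", n_excluded)
    t = np.zeros(patient.shape)
    denom = sd[valid] * np.sqrt(1.0 + 1.0 / n)
    t[valid] = (patient.data[valid] - mean[valid]) / denom
    return TMap(t=t, df=n - 1, affine=patient.affine.copy(), space="group", valid=valid)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _clusters_from_mask(mask: np.ndarray, t: np.ndarray, connectivity: int, min_size: int):
    labeled, n_lab = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n_lab + 1):
        voxels = np.argwhere(labeled == lab)
        if len(voxels) < min_size:
            continue
        tv = t[tuple(voxels.T)]
        peak = voxels[np.argmin(tv)]
        clusters.append(
            VoxelCluster(
                voxels=voxels,
                peak_voxel=tuple(int(x) for x in peak),
                peak_t=float(tv.min()),
                mean_t=float(tv.mean()),
            )
        )
    clusters.sort(key=lambda c: c.mean_t)
    return clusters


def threshold_tmap(
    tmap: TMap, settings: TMapSettings | None = None
) -> tuple[list[VoxelCluster], int]:
    """Lower-tail threshold ladder; returns (clusters, rung_used).

    Rung 1: p < ``p_primary`` with cluster extent >= k; rung 2: the same
    at ``p_fallback``; rung 3: the single global-minimum-t voxel.  A rung
    is conclusive when at least one cluster survives.
    """
    settings = settings or TMapSettings()
    valid = tmap.valid if tmap.valid is not None else np.ones(tmap.t.shape, bool)
    if not valid.any():
        return [], 3
    for rung, p in ((1, settings.p_primary), (2, settings.p_fallback)):
        t_crit = stats.t.ppf(p, tmap.df)
        mask = (tmap.t < t_crit) & valid
        clusters = _clusters_from_mask(
            mask, tmap.t, settings.connectivity, settings.cluster_extent_k
        )
        if clusters:
            return clusters, rung
    t_masked = np.where(valid, tmap.t, np.inf)
    peak = np.unravel_index(np.argmin(t_masked), tmap.t.shape)
    cluster = VoxelCluster(
        voxels=np.array([peak]),
        peak_voxel=tuple(int(x) for x in peak),
        peak_t=float(tmap.t[peak]),
        mean_t=float(tmap.t[peak]),
    )
    return [cluster], 3


def inverse_normalize(tmap: TMap, warp: WarpField) -> TMap:
    """Resample a group-space t-map back to native space (inverse warp).

    The statistic is interpolated trilinearly; categorical masks derived
    from it should instead be resampled with nearest neighbor
    (``warp.apply(..., order=0)``) so labels are preserved.
    """
    native = warp.apply(VolumeImage(tmap.t, tmap.affine), inverse=True, order=1)
    valid_native = None
    if tmap.valid is not None:
        v = warp.apply(
            VolumeImage(tmap.valid.astype(np.float64), tmap.affine), inverse=True, order=0
        )
        valid_native = v.data > 0.5
    return TMap(
        t=native.data,
        df=tmap.df,
        affine=tmap.affine.copy(),
        space="native",
        valid=valid_native,
    )
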