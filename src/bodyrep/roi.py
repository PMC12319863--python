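"""Sphere ROIs on a voxel grid: localization and condition-mean extraction.

ROIs are small spheres (default 8 mm diameter) centered on coordinates
taken from prior work, applied to individual t maps at an uncorrected
threshold. A voxel belongs to the sphere when its center lies within the
radius of the ROI center (inclusive) — the grid edge-handling rule is a
package convention, stated here because sphere membership at 2 mm
resolution is sensitive to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as sps

from .cohort import VoxelPatternSet
from .conditions import BODY_PARTS


@dataclass(frozen=True)
class ROISpec:
    """Sphere ROI: center in mm (MNI-style), diameter in mm, grid geometry."""

    center: tuple[float, float, float]
    diameter: float = 8.0
    voxel_size: float = 2.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("diameter must be >= 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be > 0")


@dataclass
class ROIResult:
    """Individual localizer outcome within one sphere."""

    responder: bool
    peak_coordinate_mm: tuple[float, float, float] | None
    peak_t: float
    extent_voxels: int
    extent_mm3: float
    threshold: float
    condition_means: np.ndarray | None = None


def sphere_voxels(spec: ROISpec) -> np.ndarray:
    """Integer voxel indices (N, 3) whose centers fall within the sphere.

    Voxel index v maps to the mm coordinate origin + v * voxel_size.
    Membership is ||center(v) - center|| <= diameter / 2, inclusive.
    """
    radius = spec.diameter / 2.0
    center = np.asarray(spec.center, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    center_vox = (center - origin) / spec.voxel_size
    reach = int(np.floor(radius / spec.voxel_size)) + 1
    lo = np.floor(center_vox).astype(int) - reach
    hi = np.ceil(center_vox).astype(int) + reach
    grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    mm = origin + idx * spec.voxel_size
    dist = np.linalg.norm(mm - center, axis=1)
    keep = idx[dist <= radius + 1e-9]
    return keep


def voxels_to_flat(voxels: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Flatten (N, 3) voxel indices into C-order flat indices for ``shape``."""
    voxels = np.asarray(voxels)
    if (voxels < 0).any() or (voxels >= np.asarray(shape)).any():
        raise ValueError("sphere extends outside the voxel grid")
    return np.ravel_multi_index(tuple(voxels.T), shape)


def localize_individual_roi(
    t_map: np.ndarray,
    spec: ROISpec,
    df: int,
    alpha: float = 0.01,
) -> ROIResult:
    """Threshold a t map inside the sphere at the upper-alpha t quantile.

    A subject is a responder when any sphere voxel exceeds the threshold;
    the peak is the maximum-t voxel and extent the suprathreshold count
    (also reported in mm^3 as count x voxel volume).
    """
    t_map = np.asarray(t_map, dtype=float)
    vox = sphere_voxels(spec)
    flat = voxels_to_flat(vox, t_map.shape)  # raises if sphere leaves the map
    t_vals = t_map.ravel()[flat]
    threshold = float(sps.t.ppf(1 - alpha, df))
    finite = np.nan_to_num(t_vals, nan=-np.inf)
    supra = finite > threshold
    extent = int(supra.sum())
    if extent == 0:
        return ROIResult(False, None, float(np.max(finite)), 0, 0.0, threshold)
    peak_idx = int(np.argmax(finite))
    peak_mm = tuple(
        np.asarray(spec.origin) + vox[peak_idx] * spec.voxel_size
    )
    return ROIResult(
        responder=True,
        peak_coordinate_mm=peak_mm,
        peak_t=float(finite[peak_idx]),
        extent_voxels=extent,
        extent_mm3=extent * spec.voxel_size**3,
        threshold=threshold,
    )


def extract_condition_means(
    patterns: VoxelPatternSet, voxels: np.ndarray
) -> np.ndarray:
    """Mean beta per body-part condition over the ROI voxels and all runs.

    Returns an 8-vector in canonical body-part order; the whole-body and
    chair localizer conditions are excluded. ``voxels`` are flat indices
    into the pattern set's voxel axis.
    """
    voxels = np.asarray(voxels)
    if voxels.size == 0:
        raise ValueError("empty voxel set")
    idx = [patterns.condition_index(c) for c in BODY_PARTS]
    return patterns.betas[:, idx][:, :, voxels].mean(axis=(0, 2))
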