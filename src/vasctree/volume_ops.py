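"""Volume preprocessing: VOI extraction, tricubic resampling, segmentation
and the minimal-distance-from-edge map that drives centerline tracking.

The auxiliary resolution for measurement is 0.2 mm isotropic; the distance
map is the exact Euclidean distance transform in physical units, i.e. each
inside voxel holds the distance to the nearest background-voxel center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

log = logging.getLogger(__name__)


@dataclass
class SegmentationMask:
    """Boolean grid aligned to a source volume (True = vessel)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    threshold_low: float

    @property
    def shape(self):
        return self.data.shape


def extract_voi(volume: Volume, box: tuple) -> Volume:
    """Crop to the axis-aligned physical box ``(lo_xyz, hi_xyz)`` in mm."""
    lo = np.asarray(box[0], dtype=float)
    hi = np.asarray(box[1], dtype=float)
    vlo, vhi = volume.extent
    lo = np.maximum(lo, vlo)
    hi = np.minimum(hi, vhi)
    if np.any(lo > hi):
        raise ValueError("VOI box does not intersect the volume")
    i0 = np.floor((lo - volume.origin) / volume.spacing + 1e-9).astype(int)
    i1 = np.ceil((hi - volume.origin) / volume.spacing - 1e-9).astype(int)
    i1 = np.maximum(i1, i0 + 1)  # keep >= 2 voxels per axis
    i1 = np.minimum(i1, np.array(volume.shape) - 1)
    i0 = np.minimum(i0, i1 - 1)
    data = volume.data[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
    return Volume(data.copy(), volume.spacing.copy(),
                  volume.origin + i0 * volume.spacing)


def resample_tricubic(volume: Volume, target_spacing: float) -> Volume:
    """Resample onto an isotropic grid using tricubic spline interpolation.

    The output grid starts at the input origin and covers the same physical
    extent; constants and linear ramps are reproduced exactly (up to spline
    round-off) away from the borders.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if target_spacing > np.max(volume.spacing):
        log.info("resampling to coarser spacing %.3g mm", target_spacing)
    lo, hi = volume.extent
    ns = np.floor((hi - lo) / target_spacing + 1e-9).astype(int) + 1
    axes = [lo[k] + target_spacing * np.arange(ns[k]) for k in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grid])
    idx = (pts - volume.origin[:, None]) / volume.spacing[:, None]
    data = ndimage.map_coordinates(
        np.ascontiguousarray(volume.data, dtype=np.float64), idx,
        order=3, mode="nearest").reshape(tuple(ns))
    return Volume(data.astype(np.float32), np.full(3, float(target_spacing)),
                  lo.copy())


def segment_threshold(volume: Volume, low: float = 150.0) -> SegmentationMask:
    """Threshold segmentation: vessel = value >= ``low`` (HU).

    The working range for contrast-enhanced studies is [100, 150]; values
    outside produce a warning only.  No connected-component selection is
    applied here — callers decide.
    """
    if not (100.0 <= low <= 150.0):
        warnings.warn(f"threshold {low} HU outside the usual [100, 150] range")
    return SegmentationMask(volume.data >= low, volume.spacing.copy(),
                            volume.origin.copy(), float(low))


def largest_component(mask: SegmentationMask,
                      containing: np.ndarray | None = None) -> SegmentationMask:
    """Keep one connected component: the largest, or the one containing a
    given physical point."""
    lab, n = ndimage.label(mask.data)
    if n == 0:
        raise ValueError("empty mask")
    if containing is not None:
        idx = np.round((np.asarray(containing) - mask.origin)
                       / mask.spacing).astype(int)
        idx = np.clip(idx, 0, np.array(mask.shape) - 1)
        want = lab[tuple(idx)]
        if want == 0:
            want = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    else:
        want = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return SegmentationMask(lab == want, mask.spacing.copy(),
                            mask.origin.copy(), mask.threshold_low)


def distance_map(mask: SegmentationMask) -> Volume:
    """Exact Euclidean distance transform in mm (anisotropy honored).

    Zero outside the mask; the maximum over a tubular mask approximates the
    tube radius (half-voxel bias from the voxel-center convention).
    """
    if not np.any(mask.data):
        raise ValueError("empty mask has no distance map")
    d = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    return Volume(d.astype(np.float32), mask.spacing.copy(),
                  mask.origin.copy())
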