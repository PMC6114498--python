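"""3-D scalar volumes with physical spacing and origin.

All geometry in this package is done in physical millimetre coordinates.
A :class:`Volume` stores its data in ``(x, y, z)`` index order; the physical
position of voxel ``(i, j, k)`` is ``origin + index * spacing`` (0-based
indices).  File IO goes through SimpleITK, which round-trips spacing and
origin for NIfTI, NRRD and MetaImage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """A 3-D scalar grid (HU or mm) with physical spacing/origin in mm."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")
        if min(self.data.shape) < 2:
            raise ValueError("grid dimensions must be >= 2 per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounds (lo, hi) spanned by voxel centers, mm."""
        hi = self.origin + (np.array(self.data.shape) - 1) * self.spacing
        return self.origin.copy(), hi

    def to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) to fractional voxel indices."""
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing

    def to_physical(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy())


class TricubicSampler:
    """Tricubic interpolation of a :class:`Volume` at arbitrary physical points.

    The cubic B-spline coefficients are computed once (``spline_filter``); each
    query is then a ``map_coordinates`` call with ``prefilter=False``, which is
    cheap enough for per-point use inside iterative searches.  Values outside
    the grid are clamped to the nearest voxel.
    """

    def __init__(self, volume: Volume):
        self.volume = volume
        self._coeff = ndimage.spline_filter(
            np.ascontiguousarray(volume.data, dtype=np.float64), order=3,
            mode="nearest")

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = self.volume.to_index(pts)
        vals = ndimage.map_coordinates(
            self._coeff, idx.T, order=3, prefilter=False, mode="nearest")
        return vals if np.asarray(points_mm).ndim > 1 else float(vals[0])

    def gradient(self, point_mm: np.ndarray, h: float = 0.05) -> np.ndarray:
        """Central-difference gradient (per mm) at one physical point."""
        p = np.asarray(point_mm, dtype=float)
        probes = np.vstack([p + h * e for e in np.eye(3)] +
                           [p - h * e for e in np.eye(3)])
        v = self(probes)
        return (v[:3] - v[3:]) / (2.0 * h)


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI / NRRD / MetaImage file into a :class:`Volume`."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    # sitk arrays come back (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write to NIfTI (.nii/.nii.gz), NRRD (.nrrd) or MetaImage (.mha/.mhd)."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))
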