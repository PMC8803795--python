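"""3-D standardized-uptake-value (SUV) volumes.

An :class:`SuvVolume` is the substrate for all lesion delineation: a 3-D
scalar grid of non-negative SUVs together with the physical voxel spacing
(mm) and the world position of the ``[0, 0, 0]`` voxel. Grid indices are
0-based; the world coordinate of voxel ``(i, j, k)`` is
``origin_mm + index * spacing_mm`` (voxel centers sit on the index lattice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["SuvVolume"]


@dataclass
class SuvVolume:
    """A 3-D SUV grid with voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative, finite SUVs (unitless normalized uptake).
    spacing_mm : tuple of 3 floats
        Strictly positive voxel spacing along each axis, in millimetres.
    origin_mm : tuple of 3 floats
        World coordinate of voxel ``(0, 0, 0)``, in millimetres.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"SUV grid must be 3-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV grid contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("SUV grid contains negative values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of the voxel centers at ``indices`` (N, 3)."""
        return np.asarray(self.origin_mm) + np.asarray(indices) * np.asarray(
            self.spacing_mm
        )

    def contains_index(self, index) -> bool:
        return all(0 <= i < n for i, n in zip(index, self.shape))

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str) -> None:
        """Write the volume as NIfTI; spacing goes into the affine diagonal."""
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "SuvVolume":
        img = nib.load(path)
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin)
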