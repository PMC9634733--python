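"""Minimal 3-D volume container shared by every pipeline stage.

A :class:`VolumeGrid` couples a scalar array with its voxel spacing and an
affine, which is all the geometry the labeling pipeline needs.  Volumes are
read and written as NIfTI through nibabel so they interoperate with standard
neuroimaging tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid"]


@dataclass
class VolumeGrid:
    """A 3-D scalar field on a regular anisotropic grid.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``; intensities, a binary mask, or
        integer class indices depending on the stage.
    spacing
        Voxel edge lengths in mm, one per axis.
    affine
        Voxel-to-world affine.  Defaults to a diagonal scaling by
        ``spacing`` so mm coordinates equal ``index * spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new volume on this grid carrying ``data``."""
        return VolumeGrid(data, self.spacing, self.affine.copy())

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (``(n, 3)`` or ``(3,)``) to mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        hom = np.c_[idx, np.ones(len(idx))]
        return (hom @ self.affine.T)[:, :3]

    # -- NIfTI round trip ---------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VolumeGrid":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), zooms, np.asarray(img.affine))
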