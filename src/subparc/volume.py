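"""Scalar volumes: a 3D grid plus a voxel-to-world affine.

All geometry in this package lives in world millimetres; the NIfTI-style
4x4 affine is the single authority for voxel<->world conversion. Voxel
indices are 0-based and refer to voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from subparc.errors import DataError

__all__ = ["ScalarVolume"]


@dataclass
class ScalarVolume:
    """A 3D scalar field with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (I, J, K)
        Scalar values; float for probability/MD/FA maps, int for labels.
    affine : ndarray, shape (4, 4)
        Maps homogeneous voxel indices (centres) to world mm.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DataError(f"expected 3D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise DataError(f"affine must be 4x4, got {self.affine.shape}")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean mask of points whose containing voxel lies in the grid."""
        ijk = np.rint(self.world_to_voxel(xyz)).astype(int)
        return np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)

    # -- sampling -----------------------------------------------------------

    def sample_world(self, xyz: np.ndarray, interpolation: str = "trilinear") -> np.ndarray:
        """Sample the field at world coordinates.

        Points outside the grid return NaN. ``interpolation`` is
        ``"trilinear"`` or ``"nearest"``.
        """
        vox = self.world_to_voxel(xyz)
        order = {"trilinear": 1, "nearest": 0}.get(interpolation)
        if order is None:
            raise DataError(f"unknown interpolation {interpolation!r}")
        out = map_coordinates(
            self.data.astype(float), vox.T, order=order, mode="constant", cval=np.nan
        )
        # map_coordinates clamps nothing: points beyond the last voxel centre
        # already blend with cval NaN; mark fully-outside points explicitly
        outside = np.any((vox < -0.5) | (vox > np.array(self.shape) - 0.5), axis=1)
        out[outside] = np.nan
        return out

    def label_at_world(self, xyz: np.ndarray) -> np.ndarray:
        """Integer label of the voxel containing each point (0 outside grid)."""
        ijk = np.rint(self.world_to_voxel(xyz)).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        labels = np.zeros(len(ijk), dtype=int)
        idx = ijk[inside]
        labels[inside] = self.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(int)
        return labels

    # -- arithmetic helpers -------------------------------------------------

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        return replace(self, data=data)

    def same_grid(self, other: "ScalarVolume", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def load(cls, path) -> "ScalarVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine))

    def save(self, path) -> None:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        nib.save(nib.Nifti1Image(data, self.affine), str(path))
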