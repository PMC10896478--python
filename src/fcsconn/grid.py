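"""Voxel grids: the grey-matter mask and the voxel-index -> mm coordinate map.

All spatial reasoning in the package (Euclidean distances between voxels,
smoothing kernels, cluster volumes) is expressed in millimetres through a
:class:`MaskedVolumeGrid`, which couples a boolean 3D mask with an isotropic
voxel size. Coordinates are 0-based voxel indices scaled by the voxel size;
all subjects of a cohort share one grid (a common reference space), so no
subject-specific warping is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np


class GridError(ValueError):
    """Raised for malformed masks or out-of-mask voxel queries."""


@dataclass(frozen=True)
class MaskedVolumeGrid:
    """A boolean 3D mask plus isotropic voxel size in mm.

    Parameters
    ----------
    mask
        Boolean 3D array; ``True`` marks in-mask (grey-matter) voxels.
    voxel_size_mm
        Isotropic voxel edge length in millimetres (default 3.0).
    """

    mask: np.ndarray
    voxel_size_mm: float = 3.0
    name: str = field(default="grid", compare=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise GridError(f"mask must be 3D, got {mask.ndim}D")
        if not np.any(mask):
            raise GridError("mask is empty")
        if not self.voxel_size_mm > 0:
            raise GridError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (the N_voxels of the FCS normalization)."""
        return int(self.mask.sum())

    @cached_property
    def voxel_indices(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel indices in C order of the mask."""
        return np.argwhere(self.mask)

    @cached_property
    def voxel_coordinates_mm(self) -> np.ndarray:
        """(n_voxels, 3) spatial coordinates = voxel index * voxel size."""
        return self.voxel_indices.astype(float) * self.voxel_size_mm

    def contains(self, ijk) -> bool:
        ijk = tuple(int(v) for v in ijk)
        if any(v < 0 or v >= s for v, s in zip(ijk, self.shape)):
            return False
        return bool(self.mask[ijk])

    def flat_index(self, ijk) -> int:
        """Position of voxel ``ijk`` within the masked-voxel ordering."""
        if not self.contains(ijk):
            raise GridError(f"voxel {tuple(ijk)} is outside the mask")
        order = np.ravel_multi_index(tuple(int(v) for v in ijk), self.shape)
        flat = np.flatnonzero(self.mask.ravel())
        return int(np.searchsorted(flat, order))

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked-voxel vector back into a full 3D volume."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise GridError(
                f"expected {self.n_voxels} masked values, got {values.shape[-1]}"
            )
        vol = np.full(values.shape[:-1] + self.shape, fill, dtype=float)
        vol[..., self.mask] = values
        return vol

    def mask_values(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask voxel values from a full 3D volume."""
        volume = np.asarray(volume)
        if volume.shape[-3:] != self.shape:
            raise GridError(
                f"volume shape {volume.shape} does not match grid {self.shape}"
            )
        return volume[..., self.mask]


def pairwise_distance_mm(grid: MaskedVolumeGrid, i, j) -> float:
    """Euclidean distance in mm between two in-mask voxels given as ijk triples.

    Symmetric, and zero iff ``i == j``; raises :class:`GridError` when either
    voxel lies outside the mask.
    """
    for v in (i, j):
        if not grid.contains(v):
            raise GridError(f"voxel {tuple(v)} is outside the mask")
    a = np.asarray(i, dtype=float) * grid.voxel_size_mm
    b = np.asarray(j, dtype=float) * grid.voxel_size_mm
    return float(np.linalg.norm(a - b))
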