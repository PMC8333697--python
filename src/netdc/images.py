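"""In-memory image containers: 4D BOLD series and 3D scalar maps.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)`` in array order;
* world coordinates are millimetres, ``world = affine @ (i, j, k, 1)``;
* values outside the analysis mask of a :class:`VolumeMap` are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, InputError

#: Recognised map kinds (informational; not enforced as an enum).
MAP_KINDS = ("dc_count", "dc_z", "fc_r", "fc_z", "t_stat", "p_value", "weight")


@dataclass
class BoldSeries:
    """One subject's 4D BOLD signal.

    Parameters
    ----------
    data:
        Array of shape ``(x, y, z, t)``.
    affine:
        4x4 voxel-to-world transform in mm; must be invertible.
    tr:
        Repetition time (sampling interval) in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise InputError(f"BoldSeries.data must be 4D, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise InputError("BoldSeries.affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise InputError("BoldSeries.affine must be invertible")
        if self.tr <= 0:
            raise InputError(f"repetition time must be positive, got {self.tr}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Return a copy carrying ``data`` with the same affine and TR."""
        return BoldSeries(data=data, affine=self.affine.copy(), tr=self.tr)


@dataclass
class VolumeMap:
    """A 3D scalar map defined on a masked grid (NaN outside the mask)."""

    data: np.ndarray
    affine: np.ndarray
    kind: str = "dc_z"
    mask_ref: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise InputError(f"VolumeMap.data must be 3D, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise InputError("VolumeMap.affine must be 4x4")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape


def check_same_grid(*objs) -> None:
    """Raise :class:`GridMismatchError` unless all objects share shape+affine.

    Accepts any mix of BoldSeries, VolumeMap and (shape, affine) pairs.
    """
    shapes, affines = [], []
    for o in objs:
        if isinstance(o, BoldSeries):
            shapes.append(o.grid_shape)
            affines.append(o.affine)
        elif isinstance(o, VolumeMap):
            shapes.append(o.grid_shape)
            affines.append(o.affine)
        else:
            shape, affine = o
            shapes.append(tuple(shape))
            affines.append(np.asarray(affine))
    ref_shape, ref_affine = shapes[0], affines[0]
    for shape, affine in zip(shapes[1:], affines[1:]):
        if shape != ref_shape:
            raise GridMismatchError(f"grid shape mismatch: {shape} vs {ref_shape}")
        if not np.allclose(affine, ref_affine, atol=1e-6):
            raise GridMismatchError("affine mismatch between volumes")


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths in mm (column norms of the 3x3 affine block)."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def world_coordinates(affine: np.ndarray, ijk) -> np.ndarray:
    """Map 0-based voxel indices to world mm through the affine."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
    homog = np.c_[ijk, np.ones(len(ijk))]
    world = homog @ np.asarray(affine).T
    return world[:, :3].squeeze()


def default_affine(spacing_mm: float = 3.0, shape=(16, 16, 16)) -> np.ndarray:
    """Isotropic affine with the world origin at the grid centre."""
    aff = np.diag([spacing_mm] * 3 + [1.0])
    aff[:3, 3] = -spacing_mm * (np.asarray(shape, dtype=float) - 1) / 2.0
    return aff
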