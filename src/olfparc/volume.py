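"""Core volumetric containers.

A :class:`Bold4D` is one subject's gridded BOLD time series: a float array
indexed ``(x, y, z, t)`` together with the voxel-to-mm affine and the
repetition time.  All pipeline stages consume and return this container so
that geometry travels with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Bold4D:
    """One subject's 4D BOLD volume.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Gridded time series.  Must be finite throughout.
    affine : ndarray, shape (4, 4)
        Voxel-to-mm map (NIfTI convention).
    repetition_time_s : float
        Time between successive frames, seconds.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    repetition_time_s: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D data must be 4D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Bold4D data contains non-finite values")
        if self.repetition_time_s <= 0:
            raise ValueError("repetition_time_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine's linear part."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "Bold4D":
        """Return a copy carrying ``data`` with the same geometry."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


def check_mask(mask: np.ndarray, shape: tuple[int, int, int], name: str = "mask") -> np.ndarray:
    """Validate a boolean 3D mask against a grid shape and return it as bool."""
    mask = np.asarray(mask)
    if mask.shape != tuple(shape):
        raise ValueError(f"{name} shape {mask.shape} does not match grid {tuple(shape)}")
    return mask.astype(bool)


def mask_coordinates(mask: np.ndarray) -> np.ndarray:
    """Voxel coordinates of a mask in the canonical ordering.

    Ordering is ascending linear index with x fastest, then y, then z
    (Fortran order over the grid), so matrix layouts are reproducible
    across runs.
    """
    idx = np.nonzero(np.asarray(mask, dtype=bool).ravel(order="F"))[0]
    x, y, z = np.unravel_index(idx, mask.shape, order="F")
    return np.column_stack([x, y, z]).astype(np.int64)


def series_at(data4d: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Extract (n_voxels, t) time series at integer voxel coordinates."""
    return data4d[coords[:, 0], coords[:, 1], coords[:, 2], :]
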