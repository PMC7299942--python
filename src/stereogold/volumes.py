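"""Voxel-grid containers shared by the whole pipeline.

Arrays are stored in ``(z, y, x)`` index order (the natural order of a serial
EM stack: one XY image per milling step).  Physical voxel sizes are carried as
an ``(x, y, z)`` triple in nanometres because FIB-SEM data are strongly
anisotropic (the milling step is typically 4-8x the XY pixel).  All physical
point coordinates handed around the pipeline are ``(x, y, z)`` in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelVolume", "ImageStack", "voxel_centers_um"]


def _check_voxel_size(voxel_size) -> np.ndarray:
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (3,):
        raise ValueError(f"voxel_size must be an (x, y, z) triple, got shape {vs.shape}")
    if not np.all(vs > 0):
        raise ValueError(f"voxel_size components must be strictly positive, got {vs}")
    return vs


@dataclass
class LabelVolume:
    """3D grid of non-negative integer object labels; 0 is background.

    Parameters
    ----------
    data
        Integer array of shape ``(nz, ny, nx)``.
    voxel_size
        Physical voxel edge lengths ``(x, y, z)`` in nm.
    """

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label data must be integer, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted distinct nonzero labels present in the grid."""
        u = np.unique(self.data)
        return u[u != 0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and bool(np.array_equal(self.data, other.data))
            and bool(np.allclose(self.voxel_size, other.voxel_size))
        )


@dataclass
class ImageStack:
    """3D grid of 8-bit intensities (a serial EM stack), shape ``(nz, ny, nx)``."""

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3D, got ndim={self.data.ndim}")
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def voxel_centers_um(indices_zyx: np.ndarray, voxel_size_nm) -> np.ndarray:
    """Map voxel indices ``(z, y, x)`` to physical voxel-center coordinates.

    Voxel ``(i, j, k)`` (in x, y, z order) is centred at
    ``((i + 1/2) dx, (j + 1/2) dy, (k + 1/2) dz)``, which keeps centroid math
    independent of the grid origin.  Returns an ``(n, 3)`` array of
    ``(x, y, z)`` micrometre coordinates.
    """
    idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
    vs = _check_voxel_size(voxel_size_nm)
    xyz = idx[:, ::-1] + 0.5  # zyx -> xyz, half-voxel offset to the centre
    return xyz * vs / 1000.0
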