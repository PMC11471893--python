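"""Core density-volume container.

A :class:`TomogramVolume` is a 3D scalar density grid with an isotropic
physical voxel size in Ångström, indexed ``densities[x, y, z]``.  The beam /
viewing direction of the (real or simulated) tomogram is the z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TomogramVolume"]


@dataclass
class TomogramVolume:
    """3D density grid with physical voxel size.

    Parameters
    ----------
    densities : ndarray, shape (nx, ny, nz)
        Scalar densities, indexed ``[x, y, z]``; must be finite.
    voxel_size : float
        Isotropic voxel edge length in Å (> 0).
    origin : ndarray, shape (3,)
        Physical position (Å) of voxel (0, 0, 0).
    """

    densities: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities)
        if self.densities.ndim != 3:
            raise ValueError("densities: expected a 3D array, got "
                             f"{self.densities.ndim}D")
        if any(n < 1 for n in self.densities.shape):
            raise ValueError("densities: all dims must be >= 1, got "
                             f"{self.densities.shape}")
        if not np.all(np.isfinite(self.densities)):
            raise ValueError("densities: non-finite values present")
        if not (np.isscalar(self.voxel_size) or np.ndim(self.voxel_size) == 0) \
                or not float(self.voxel_size) > 0:
            raise ValueError(f"voxel_size: must be > 0, got {self.voxel_size}")
        self.voxel_size = float(self.voxel_size)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin: expected a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.densities.shape

    @property
    def physical_extent(self) -> np.ndarray:
        """Edge lengths of the grid in Å."""
        return np.asarray(self.shape) * self.voxel_size

    def copy_with(self, densities: np.ndarray) -> "TomogramVolume":
        """New volume sharing voxel size / origin with different densities."""
        return TomogramVolume(densities, self.voxel_size, self.origin.copy())
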