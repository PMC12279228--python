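"""Voxelized optical-parameter volume.

A :class:`VoxelGrid` stores the per-voxel index-ellipsoid parameters on a
regular (nx, ny, nz) raster in the object frame (x, y, z): c-axis angles
``phi`` (polar, [0, pi]) and ``psi`` (azimuthal, [0, 2 pi)), extraordinary
index ``n_e``, and an absorption coefficient ``absorption`` expressed per
voxel traversal (Beer-Lambert: a straight path of length ``L`` voxels
transmits ``exp(-A * L)``).

The ordinary index ``n_o`` is a global constant (that of the index-matching
liquid), never a per-voxel unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import c_axis_vector

__all__ = ["VoxelGrid"]

#: ballistic small-birefringence bound |n_e - n_o| for the straight-ray model
MAX_BIREFRINGENCE = 1e-2


@dataclass
class VoxelGrid:
    phi: np.ndarray
    psi: np.ndarray
    n_e: np.ndarray
    absorption: np.ndarray = None  # type: ignore[assignment]
    n_o: float = 1.48
    voxel_size_um: float = 23.44
    wavelength_um: float = 0.625

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.n_e = np.asarray(self.n_e, dtype=float)
        if self.absorption is None:
            self.absorption = np.zeros_like(self.phi)
        self.absorption = np.asarray(self.absorption, dtype=float)
        shapes = {a.shape for a in (self.phi, self.psi, self.n_e, self.absorption)}
        if len(shapes) != 1 or self.phi.ndim != 3:
            raise ValueError("parameter arrays must share one 3D shape")
        if np.any(np.abs(self.n_e - self.n_o) > MAX_BIREFRINGENCE + 1e-12):
            raise ValueError(
                "n_e outside the ballistic regime |n_e - n_o| <= 1e-2"
            )
        if np.any(self.absorption < 0):
            raise ValueError("absorption must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phi.shape  # type: ignore[return-value]

    @property
    def birefringence(self) -> np.ndarray:
        """Per-voxel Delta n = n_e - n_o."""
        return self.n_e - self.n_o

    def c_axis(self) -> np.ndarray:
        """Per-voxel unit c-axis directors, shape (nx, ny, nz, 3)."""
        return c_axis_vector(self.phi, self.psi)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(
            phi=self.phi.copy(),
            psi=self.psi.copy(),
            n_e=self.n_e.copy(),
            absorption=self.absorption.copy(),
            n_o=self.n_o,
            voxel_size_um=self.voxel_size_um,
            wavelength_um=self.wavelength_um,
        )

    @classmethod
    def empty(
        cls,
        shape: tuple[int, int, int],
        n_o: float = 1.48,
        voxel_size_um: float = 23.44,
        wavelength_um: float = 0.625,
    ) -> "VoxelGrid":
        """Isotropic, transparent grid (n_e = n_o, A = 0 everywhere)."""
        z = np.zeros(shape)
        return cls(
            phi=z.copy(),
            psi=z.copy(),
            n_e=np.full(shape, n_o),
            absorption=z.copy(),
            n_o=n_o,
            voxel_size_um=voxel_size_um,
            wavelength_um=wavelength_um,
        )
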