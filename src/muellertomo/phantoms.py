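"""Ground-truth phantoms and synthetic measurement generation.

The principal validation object is a helical (spiral) tube: its c-axis
field follows the local helix tangent, the birefringence Delta n ramps
smoothly along the helix over [0.001, 0.002] and the absorption over
[0.1, 0.3] per voxel — magnitudes typical of collagenous biological tissue.
Projection stacks are simulated with the ballistic forward model, optionally
corrupted with 12-bit Poisson shot noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ProjectionSet, add_shot_noise, simulate_intensities
from .geometry import AcquisitionGeometry
from .grid import VoxelGrid

__all__ = [
    "SpiralPhantomSpec",
    "make_spiral",
    "spiral_centerline",
    "make_random_init",
    "make_dataset",
]


@dataclass
class SpiralPhantomSpec:
    """Geometry and optical ranges of the helical validation phantom.

    The helix axis runs along the long (y) grid dimension, centered in the
    transverse plane; a single pitch spans ``pitch_voxels``.  Voxels within
    ``tube_radius`` of the continuous centerline are foreground.
    ``helix_radius`` defaults to the largest value for which the tube still
    fits inside the grid cross-section.
    """

    shape: tuple[int, int, int] = (15, 25, 15)
    pitch_voxels: float = 22.0
    tube_radius: float = 3.0
    helix_radius: float | None = None
    handedness: str = "right"
    dn_range: tuple[float, float] = (0.001, 0.002)
    absorption_range: tuple[float, float] = (0.1, 0.3)
    n_o: float = 1.48
    voxel_size_um: float = 23.44
    wavelength_um: float = 0.625

    def __post_init__(self) -> None:
        if self.helix_radius is None:
            half = min(self.shape[0], self.shape[2]) / 2.0
            self.helix_radius = half - self.tube_radius - 0.5
        if self.helix_radius + self.tube_radius > min(self.shape[0], self.shape[2]) / 2.0:
            raise ValueError("spiral tube does not fit inside the grid")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")
        if self.dn_range[0] <= 0 or self.dn_range[1] < self.dn_range[0]:
            raise ValueError("dn_range must be positive and ordered")


def spiral_centerline(spec: SpiralPhantomSpec, s: np.ndarray):
    """Centerline points and unit tangents at arc parameter ``s`` (voxel
    units along the helix axis, 0 .. pitch)."""
    nx, ny, nz = spec.shape
    cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
    y0 = (ny - 1) / 2.0 - spec.pitch_voxels / 2.0
    # right-handed: cross(radial, tangent) . axis > 0, i.e. the angle in the
    # (x, z) plane decreases while advancing along +y in right-handed coords
    sign = -1.0 if spec.handedness == "right" else 1.0
    omega = 2.0 * np.pi / spec.pitch_voxels
    ang = sign * omega * s
    r = spec.helix_radius
    pts = np.stack(
        [cx + r * np.cos(ang), y0 + s, cz + r * np.sin(ang)], axis=-1
    )
    tans = np.stack(
        [
            -r * sign * omega * np.sin(ang),
            np.ones_like(s),
            r * sign * omega * np.cos(ang),
        ],
        axis=-1,
    )
    tans /= np.linalg.norm(tans, axis=-1, keepdims=True)
    return pts, tans


def make_spiral(spec: SpiralPhantomSpec | None = None, seed: int | None = None) -> VoxelGrid:
    """Ground-truth helical phantom.

    The c-axis of each foreground voxel is the helix tangent at the nearest
    centerline point; Delta n and the absorption ramp linearly with the
    centerline parameter over their configured ranges.  ``seed`` is accepted
    for interface uniformity (the phantom itself is deterministic).
    """
    spec = spec or SpiralPhantomSpec()
    s = np.arange(0.0, spec.pitch_voxels + 1e-9, 0.02)
    pts, tans = spiral_centerline(spec, s)

    nx, ny, nz = spec.shape
    centers = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).astype(float)
    # distance of each voxel center to the sampled centerline
    d2 = np.sum(
        (centers[..., None, :] - pts[None, None, None, :, :]) ** 2, axis=-1
    )
    nearest = np.argmin(d2, axis=-1)
    dist = np.sqrt(np.take_along_axis(d2, nearest[..., None], axis=-1))[..., 0]
    fg = dist <= spec.tube_radius

    tan_near = tans[nearest]
    phi = np.arccos(np.clip(tan_near[..., 2], -1.0, 1.0))
    psi = np.mod(np.arctan2(tan_near[..., 1], tan_near[..., 0]), 2.0 * np.pi)
    frac = s[nearest] / spec.pitch_voxels
    dn = spec.dn_range[0] + frac * (spec.dn_range[1] - spec.dn_range[0])
    absorb = spec.absorption_range[0] + frac * (
        spec.absorption_range[1] - spec.absorption_range[0]
    )

    grid = VoxelGrid(
        phi=np.where(fg, phi, 0.0),
        psi=np.where(fg, psi, 0.0),
        n_e=np.where(fg, spec.n_o + dn, spec.n_o),
        absorption=np.where(fg, absorb, 0.0),
        n_o=spec.n_o,
        voxel_size_um=spec.voxel_size_um,
        wavelength_um=spec.wavelength_um,
    )
    return grid


def make_random_init(
    shape: tuple[int, int, int],
    seed: int,
    phi_range: tuple[float, float] = (0.0, np.pi),
    psi_range: tuple[float, float] = (0.0, 2.0 * np.pi),
    dn_range: tuple[float, float] = (0.0, 0.002),
    absorption_range: tuple[float, float] = (0.0, 0.0),
    n_o: float = 1.48,
    voxel_size_um: float = 23.44,
    wavelength_um: float = 0.625,
) -> VoxelGrid:
    """Uniform i.i.d. random parameter grid, deterministic per seed."""
    rng = np.random.default_rng(seed)
    return VoxelGrid(
        phi=rng.uniform(*phi_range, size=shape),
        psi=rng.uniform(*psi_range, size=shape),
        n_e=n_o + rng.uniform(*dn_range, size=shape),
        absorption=rng.uniform(*absorption_range, size=shape),
        n_o=n_o,
        voxel_size_um=voxel_size_um,
        wavelength_um=wavelength_um,
    )


def make_dataset(
    grid: VoxelGrid,
    geometry: AcquisitionGeometry,
    noise: bool = True,
    seed: int | None = None,
    full_well: int = 4095,
) -> tuple[ProjectionSet, VoxelGrid]:
    """Synthetic measurement: forward simulation plus optional shot noise.

    Returns ``(projections, truth)`` so that recovery tests can score the
    reconstruction against the generating grid.
    """
    projections = simulate_intensities(grid, geometry)
    if noise:
        projections = add_shot_noise(projections, full_well=full_well, seed=seed)
    return projections, grid
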