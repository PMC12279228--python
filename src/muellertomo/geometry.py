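"""Acquisition geometry: tomographic angle sets, detector raster and the
bookkeeping identities that relate scan settings to dataset size.

Angles are stored in radians internally; file formats and the CLI use
degrees.  The default scan mirrors a dual-axis goniometer acquisition:
rotation angles alpha in 14-degree steps over a full turn (26 values) at
tilt angles beta of 0 and +/-6.8 degrees, i.e. 78 projections, each measured
in 16 polarization sets (4 PSG x 4 PSA states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "default_scan_angles",
    "count_datapoints",
    "object_plane_resolution",
    "effective_voxel_size",
]

#: Number of polarization sets per projection (4 generator x 4 analyzer).
N_POL_SETS = 16


def default_scan_angles(
    rotation_step_deg: float = 14.0,
    tilts_deg: tuple[float, ...] = (0.0, 6.8, -6.8),
) -> np.ndarray:
    """(alpha, beta) pairs in radians for the default dual-axis scan.

    Rotations run from 0 (inclusive) to 360 degrees (exclusive); every
    rotation is repeated at each tilt.
    """
    alphas = np.arange(0.0, 360.0, rotation_step_deg)
    pairs = [(a, b) for b in tilts_deg for a in alphas]
    return np.deg2rad(np.array(pairs))


@dataclass
class AcquisitionGeometry:
    """Geometry of one tomographic polarimetric scan.

    Parameters
    ----------
    wavelength_um : illumination wavelength in micrometers.
    voxel_size_um : isotropic voxel pitch ``d``; the detector pixel pitch is
        matched to it (one ballistic ray per pixel).
    n_o : ordinary refractive index, fixed to the immersion-liquid value.
    angles : array (n_proj, 2) of (alpha, beta) in radians.
    """

    wavelength_um: float = 0.625
    voxel_size_um: float = 23.44
    n_o: float = 1.48
    angles: np.ndarray = field(default_factory=default_scan_angles)

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.shape[1] != 2:
            raise ValueError("angles must be an (n_proj, 2) array")
        if self.wavelength_um <= 0 or self.voxel_size_um <= 0 or self.n_o <= 0:
            raise ValueError("wavelength, voxel size and n_o must be positive")

    @property
    def n_projections(self) -> int:
        return self.angles.shape[0]


def object_plane_resolution(
    camera_pixel_um: float = 5.86, magnification: float = 2.0
) -> float:
    """Object-plane sampling of the camera: pixel pitch / magnification."""
    return camera_pixel_um / magnification


def effective_voxel_size(
    camera_pixel_um: float = 5.86,
    magnification: float = 2.0,
    downsampling: int = 8,
) -> float:
    """Voxel size after detector binning, in micrometers.

    With the default 5.86-um camera pixels behind a 2x objective and 8x
    software downsampling this is 5.86 / 2 * 8 = 23.44 um.
    """
    return object_plane_resolution(camera_pixel_um, magnification) * downsampling


def count_datapoints(
    grid_shape: tuple[int, int, int],
    n_rotations: int,
    n_tilts: int,
    n_pol_sets: int = N_POL_SETS,
) -> tuple[int, int, int]:
    """Measured datapoints vs. unknowns for a scan of a given grid.

    The detector raster matches the (nx, ny) footprint of the grid, so each
    projection image has nx*ny pixels.  Returns
    ``(datapoints, parameters, parameters_with_absorption)`` where the
    parameter count is 3 unknowns (phi, psi, n_e) per voxel, or 4 including
    the absorption coefficient.
    """
    nx, ny, nz = grid_shape
    if min(nx, ny, nz, n_rotations, n_tilts, n_pol_sets) < 1:
        raise ValueError("all counts must be positive integers")
    datapoints = n_rotations * n_tilts * n_pol_sets * nx * ny
    parameters = nx * ny * nz * 3
    return datapoints, parameters, nx * ny * nz * 4
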