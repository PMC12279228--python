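"""Ballistic straight-ray polarimetric forward model.

For a projection at tomographic angles ``(alpha, beta)`` every detector
pixel receives exactly one parallel ray along the lab beam axis ``p``.  The
ray is sampled at uniform steps of one voxel pitch ``d``; at each sample the
nearest voxel of the rotated grid contributes a linear-retarder Mueller
matrix (``optics.voxel_mueller``) whose retardance and fast axis follow from
the local index ellipsoid and the incidence direction.  The cumulative
per-pixel Mueller matrix is the ordered (non-commuting) product of the
per-sample matrices, last-hit voxel leftmost:

    M(k, j) = M_N ... M_2 M_1

and the simulated intensity for polarization set l (generator state g,
analyzer state a) is

    I_l(k, j) = S^T M_a^PSA M(k, j) M_g^PSG S,   S = (1, 0, 0, 0)^T.

The detector raster matches the (nx, ny) footprint of the grid, with the
rotation axis j along y and the tilt axis k along x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionGeometry, N_POL_SETS
from .grid import VoxelGrid
from .optics import (
    POL_STATE_ORDER,
    c_axis_vector,
    pol_state_stokes,
    sample_rotation,
    voxel_mueller,
)

__all__ = [
    "ProjectionSet",
    "ForwardModel",
    "ray_voxel_path",
    "project_mueller",
    "simulate_intensities",
    "add_shot_noise",
    "pol_set_labels",
]

_EPS_TRANSVERSE = 1e-12


def pol_set_labels() -> list[tuple[str, str]]:
    """(analyzer, generator) state labels of the 16 sets, in storage order."""
    return [(a, g) for a in POL_STATE_ORDER for g in POL_STATE_ORDER]


def _state_vectors() -> tuple[np.ndarray, np.ndarray]:
    """Analyzer rows and generator columns for the 16 sets, shape (16, 4).

    ``I_l = 0.25 * va_l . M . vg_l`` with the ideal-polarizer convention
    (each polarizer carries a factor 1/2).
    """
    va = np.empty((N_POL_SETS, 4))
    vg = np.empty((N_POL_SETS, 4))
    for l, (a, g) in enumerate(pol_set_labels()):
        va[l] = pol_state_stokes(a)
        vg[l] = pol_state_stokes(g)
    return va, vg


VA_STATES, VG_STATES = _state_vectors()


@dataclass
class ProjectionSet:
    """Stack of polarization-resolved projection images.

    ``intensities`` is indexed ``[projection i, polarization set l, k, j]``
    with l ordered as in :func:`pol_set_labels`; ``angles`` holds the
    (alpha, beta) pair of each projection in radians.
    """

    intensities: np.ndarray
    angles: np.ndarray
    voxel_size_um: float = 23.44
    wavelength_um: float = 0.625
    n_o: float = 1.48
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be (n_proj, n_pol, nk, nj)")
        if self.intensities.shape[0] != self.angles.shape[0]:
            raise ValueError("one (alpha, beta) pair per projection required")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_projections(self) -> int:
        return self.intensities.shape[0]

    @property
    def detector_shape(self) -> tuple[int, int]:
        return self.intensities.shape[2:]  # type: ignore[return-value]


class ForwardModel:
    """Caches the ray sampling pattern of one grid shape + geometry.

    All lengths are handled in voxel units internally; the physical pitch
    ``d`` enters only through the retardance prefactor 2 pi d / lambda and
    the Beer-Lambert absorption per step.
    """

    def __init__(self, shape: tuple[int, int, int], geometry: AcquisitionGeometry):
        self.shape = tuple(shape)
        self.geometry = geometry
        nx, ny, nz = self.shape
        n_steps = int(np.ceil(np.sqrt(nx**2 + ny**2 + nz**2)))
        # parity-match the step count to nz so that at alpha = beta = 0 the
        # sample points coincide exactly with voxel centers
        if (n_steps - nz) % 2:
            n_steps += 1
        self.n_steps = n_steps
        self.n_pixels = nx * ny
        # voxel flat index per (projection, pixel, step); -1 = outside grid
        self._flat_idx = np.empty(
            (geometry.n_projections, self.n_pixels, n_steps), dtype=np.int64
        )
        self._rotations = np.empty((geometry.n_projections, 3, 3))
        for i, (alpha, beta) in enumerate(geometry.angles):
            rs = sample_rotation(alpha, beta)
            self._rotations[i] = rs
            self._flat_idx[i] = self._sample_indices(rs)

    def _sample_indices(self, rs: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.shape
        xs = np.arange(nx) - (nx - 1) / 2.0
        ys = np.arange(ny) - (ny - 1) / 2.0
        ts = np.arange(self.n_steps) - (self.n_steps - 1) / 2.0
        # lab-frame sample points for all pixels and steps
        px, py, pt = np.meshgrid(xs, ys, ts, indexing="ij")
        lab = np.stack([px, py, pt], axis=-1).reshape(-1, 3)
        obj = lab @ rs  # R_s^T applied to rows
        ijk = np.rint(obj + (np.array(self.shape) - 1) / 2.0).astype(np.int64)
        valid = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        flat = np.where(
            valid, np.ravel_multi_index(ijk.T % np.array(self.shape)[:, None], self.shape), -1
        )
        return flat.reshape(self.n_pixels, self.n_steps)

    # -- per-projection sample optics ------------------------------------

    def retarder_arrays(self, grid: VoxelGrid, iproj: int):
        """Per-sample (delta, theta, t_LR) plus gradient chain factors.

        Returns a dict of arrays of shape (n_pixels, n_steps).  Background
        samples (outside the grid) carry delta = 0, theta = 0, t = 1.
        Alongside the retarder parameters the partial derivatives needed by
        the analytic gradient are returned:
        d(delta)/d(phi, psi, n_e) and d(theta)/d(phi, psi).
        """
        flat = self._flat_idx[iproj]
        valid = flat >= 0
        safe = np.where(valid, flat, 0)
        phi = grid.phi.ravel()[safe]
        psi = grid.psi.ravel()[safe]
        n_e = grid.n_e.ravel()[safe]
        absorb = grid.absorption.ravel()[safe]

        rs = self._rotations[iproj]
        c = c_axis_vector(phi, psi)  # (..., 3)
        dc_dphi = np.stack(
            [
                np.cos(phi) * np.cos(psi),
                np.cos(phi) * np.sin(psi),
                -np.sin(phi),
            ],
            axis=-1,
        )
        dc_dpsi = np.stack(
            [
                -np.sin(phi) * np.sin(psi),
                np.sin(phi) * np.cos(psi),
                np.zeros_like(phi),
            ],
            axis=-1,
        )
        g = c @ rs.T
        g_phi = dc_dphi @ rs.T
        g_psi = dc_dpsi @ rs.T

        n_o = grid.n_o
        w = g[..., 2]  # cos(angle to c-axis)
        d_big = n_o**2 * (1.0 - w**2) + n_e**2 * w**2
        n_eff = n_o * n_e / np.sqrt(d_big)
        pref = 2.0 * np.pi * grid.voxel_size_um / grid.wavelength_um
        delta = pref * (n_eff - n_o)
        # dn_E/dw and dn_E/dn_e
        dne_dw = -n_o * n_e * w * (n_e**2 - n_o**2) * d_big ** (-1.5)
        dne_dne = n_o**3 * (1.0 - w**2) * d_big ** (-1.5)
        ddelta_dphi = pref * dne_dw * g_phi[..., 2]
        ddelta_dpsi = pref * dne_dw * g_psi[..., 2]
        ddelta_dne = pref * dne_dne

        gk, gj = g[..., 0], g[..., 1]
        rho2 = gk**2 + gj**2
        degenerate = rho2 < _EPS_TRANSVERSE
        theta = np.where(degenerate, 0.0, np.arctan2(gj, gk))
        rho2_safe = np.where(degenerate, 1.0, rho2)
        dtheta_dphi = np.where(
            degenerate, 0.0, (gk * g_phi[..., 1] - gj * g_phi[..., 0]) / rho2_safe
        )
        dtheta_dpsi = np.where(
            degenerate, 0.0, (gk * g_psi[..., 1] - gj * g_psi[..., 0]) / rho2_safe
        )

        t_lr = np.exp(-absorb)
        # blank out background samples
        for arr in (delta, theta, ddelta_dphi, ddelta_dpsi, ddelta_dne,
                    dtheta_dphi, dtheta_dpsi):
            arr[~valid] = 0.0
        t_lr[~valid] = 1.0
        return {
            "delta": delta,
            "theta": theta,
            "t_lr": t_lr,
            "ddelta_dphi": ddelta_dphi,
            "ddelta_dpsi": ddelta_dpsi,
            "ddelta_dne": ddelta_dne,
            "dtheta_dphi": dtheta_dphi,
            "dtheta_dpsi": dtheta_dpsi,
            "valid": valid,
            "flat": flat,
        }

    def sample_mueller(self, grid: VoxelGrid, iproj: int) -> np.ndarray:
        """Per-sample voxel Mueller matrices, shape (n_pix, n_steps, 4, 4)."""
        arrs = self.retarder_arrays(grid, iproj)
        return voxel_mueller(arrs["delta"], arrs["theta"], arrs["t_lr"])

    def mueller_chain(self, grid: VoxelGrid, iproj: int) -> np.ndarray:
        """Cumulative per-pixel Mueller matrix of projection ``iproj``."""
        m = self.sample_mueller(grid, iproj)
        total = np.broadcast_to(np.eye(4), (self.n_pixels, 4, 4)).copy()
        for step in range(self.n_steps):
            total = m[:, step] @ total
        return total

    def intensities(self, grid: VoxelGrid, iproj: int) -> np.ndarray:
        """16 polarization-set images of one projection, shape (16, nk, nj)."""
        chain = self.mueller_chain(grid, iproj)
        nx, ny, _ = self.shape
        z = chain @ VG_STATES.T  # (P, 4, 16)
        img = 0.25 * np.einsum("la,pal->lp", VA_STATES, z)
        return img.reshape(N_POL_SETS, nx, ny)

    def simulate(self, grid: VoxelGrid) -> ProjectionSet:
        nx, ny, _ = self.shape
        out = np.empty(
            (self.geometry.n_projections, N_POL_SETS, nx, ny), dtype=float
        )
        for i in range(self.geometry.n_projections):
            out[i] = self.intensities(grid, i)
        # clip tiny negative round-off
        np.clip(out, 0.0, None, out=out)
        return ProjectionSet(
            intensities=out,
            angles=self.geometry.angles.copy(),
            voxel_size_um=grid.voxel_size_um,
            wavelength_um=grid.wavelength_um,
            n_o=grid.n_o,
        )


# ---------------------------------------------------------------------------
# module-level convenience wrappers


def ray_voxel_path(
    grid: VoxelGrid, alpha: float, beta: float, pixel: tuple[int, int]
):
    """Ordered voxel indices and path lengths of one detector ray.

    Voxels are listed source-to-sensor; each carries a constant path length
    of one voxel pitch (in micrometers).  A ray missing the grid returns an
    empty path.
    """
    geom = AcquisitionGeometry(
        voxel_size_um=grid.voxel_size_um,
        wavelength_um=grid.wavelength_um,
        n_o=grid.n_o,
        angles=np.array([[alpha, beta]]),
    )
    fm = ForwardModel(grid.shape, geom)
    k, j = pixel
    nx, ny, _ = grid.shape
    if not (0 <= k < nx and 0 <= j < ny):
        raise ValueError("pixel outside detector raster")
    flat = fm._flat_idx[0][k * ny + j]
    flat = flat[flat >= 0]
    idx = np.stack(np.unravel_index(flat, grid.shape), axis=-1)
    lengths = np.full(len(flat), grid.voxel_size_um)
    return idx, lengths


def project_mueller(grid: VoxelGrid, alpha: float, beta: float) -> np.ndarray:
    """Per-pixel cumulative Mueller image, shape (nx, ny, 4, 4)."""
    geom = AcquisitionGeometry(
        voxel_size_um=grid.voxel_size_um,
        wavelength_um=grid.wavelength_um,
        n_o=grid.n_o,
        angles=np.array([[alpha, beta]]),
    )
    fm = ForwardModel(grid.shape, geom)
    nx, ny, _ = grid.shape
    return fm.mueller_chain(grid, 0).reshape(nx, ny, 4, 4)


def simulate_intensities(
    grid: VoxelGrid, geometry: AcquisitionGeometry
) -> ProjectionSet:
    """Simulate the full polarization-resolved projection stack."""
    return ForwardModel(grid.shape, geometry).simulate(grid)


def add_shot_noise(
    projections: ProjectionSet, full_well: int = 4095, seed: int | None = None
) -> ProjectionSet:
    """Poisson shot noise of an n-bit camera (default 12 bit, 4095 counts).

    Intensities are scaled so the global maximum maps to ``full_well``
    counts, Poisson-sampled, and rescaled to the original units.
    """
    img = projections.intensities
    if np.any(img < 0):
        raise ValueError("intensities must be non-negative")
    peak = img.max()
    if peak == 0:
        return ProjectionSet(
            intensities=img.copy(),
            angles=projections.angles.copy(),
            voxel_size_um=projections.voxel_size_um,
            wavelength_um=projections.wavelength_um,
            n_o=projections.n_o,
            meta=dict(projections.meta, full_well=full_well),
        )
    rng = np.random.default_rng(seed)
    scale = full_well / peak
    noisy = rng.poisson(img * scale).astype(float) / scale
    return ProjectionSet(
        intensities=noisy,
        angles=projections.angles.copy(),
        voxel_size_um=projections.voxel_size_um,
        wavelength_um=projections.wavelength_um,
        n_o=projections.n_o,
        meta=dict(projections.meta, full_well=full_well),
    )
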