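"""Inverse problem: voxel-wise index-ellipsoid reconstruction.

The unknowns are the per-voxel c-axis angles (phi, psi) and extraordinary
index n_e (n_o is fixed to the immersion-liquid value).  They are found by
minimizing the squared intensity error

    eps_I = sum_i sum_l sum_{k,j} (I_hat_li(k,j) - I_li(k,j))^2

plus smoothing regularizers on the director field and on n_e, with
analytical gradients and Nesterov-accelerated, stage-wise gradient descent
(alternating orientation and index updates).  The absorption tomogram is
reconstructed separately by linear tomography on -log(transmission): the
scalar transmission factors out of every retarder matrix, so the decoupling
is exact.

The data-fit gradient follows the chain rule through the matrix product:
for voxel sample p on the ray to pixel (k, j),

    d(eps_I)/du = sum 2 (I_hat - I) * <O_p^T W L_p^T,
                  dM/dtheta * dtheta/du + dM/ddelta * ddelta/du>

where L_p and O_p are the Mueller products of the voxels before and after p
and <.,.> is the element-wise (Frobenius) inner product; terms of voxels off
the ray vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .forward import VA_STATES, VG_STATES, ForwardModel, ProjectionSet
from .geometry import AcquisitionGeometry
from .grid import VoxelGrid
from .optics import (
    c_axis_vector,
    voxel_mueller,
    voxel_mueller_ddelta,
    voxel_mueller_dtheta,
)

__all__ = [
    "ReconConfig",
    "ReconState",
    "loss",
    "analytic_gradient",
    "smooth_reg_orientation",
    "smooth_reg_index",
    "nesterov_step",
    "reconstruct",
    "reconstruct_multistart",
    "reconstruct_absorption",
    "proximity_metrics",
]


def loss(measured: ProjectionSet, simulated: ProjectionSet) -> float:
    """Sum of squared intensity differences over all projections/sets/pixels."""
    if measured.intensities.shape != simulated.intensities.shape:
        raise ValueError("projection sets have mismatched shapes")
    diff = simulated.intensities - measured.intensities
    return float(np.sum(diff * diff))


@dataclass
class ReconConfig:
    """Optimizer settings.

    Learning rates apply to the scale-normalized objective (mean squared
    intensity error per datapoint plus mean-per-pair regularizers); see
    docs/methods.md for the normalization and the one-time line search that
    fixed the defaults.
    """

    lr_orientation: float = 8000.0
    lr_index: float = 3e-2
    momentum: float = 0.9
    n_iterations: int = 250
    block_orientation: int = 10
    block_index: int = 10
    weight_orientation: float = 3e-3
    weight_index: float = 1e-3
    dn_max: float = 0.002
    seed: int = 0
    init_phi_range: tuple[float, float] = (0.0, np.pi)
    init_psi_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    init_dn_range: tuple[float, float] = (0.0, 0.002)
    # optimization bounds on Delta n = n_e - n_o; the non-negative default
    # encodes the positive-birefringence prior and removes the conjugate
    # (delta, theta) -> (-delta, theta + pi/2) solution branch
    dn_bounds: tuple[float, float] = (0.0, 0.01)
    fit_absorption: bool = True
    patience: int = 8
    lr_backoff: float = 0.5
    plateau_rtol: float = 1e-6
    batch_projections: int | None = None  # None = full batch (deterministic GD)

    def __post_init__(self) -> None:
        if self.weight_orientation < 0 or self.weight_index < 0:
            raise ValueError("regularizer weights must be non-negative")
        if self.block_orientation < 1 or self.block_index < 1:
            raise ValueError("stage-wise block lengths must be >= 1")


@dataclass
class ReconState:
    """Result of a reconstruction run: estimate, momentum and traces."""

    grid: VoxelGrid
    traces: dict = field(default_factory=dict)
    momentum: dict = field(default_factory=dict)
    config: ReconConfig | None = None


# ---------------------------------------------------------------------------
# data-fit gradient


# outer products va_l vg_l^T of the 16 polarization sets
_VAG_OUTER = np.einsum("la,lb->lab", VA_STATES, VG_STATES)


def _batch_gradient(
    fm: ForwardModel,
    grid: VoxelGrid,
    measured_flat: np.ndarray,
    projections: np.ndarray,
    gphi: np.ndarray,
    gpsi: np.ndarray,
    gne: np.ndarray,
) -> float:
    """Accumulate d(eps_I)/d(phi, psi, n_e) of a batch of projections;
    returns their eps_I contribution.  ``measured_flat`` holds the measured
    images of the batch, shape (16, n_batch * n_pixels)."""
    per_proj = [fm.retarder_arrays(grid, int(i)) for i in projections]
    arrs = {
        key: np.concatenate([a[key] for a in per_proj], axis=0)
        for key in per_proj[0]
    }
    delta, theta, t_lr = arrs["delta"], arrs["theta"], arrs["t_lr"]
    m = voxel_mueller(delta, theta, t_lr)  # (P, S, 4, 4)
    n_pix, n_steps = delta.shape

    prefix = np.empty_like(m)  # L_s = product of samples before s
    prefix[:, 0] = np.eye(4)
    for s in range(1, n_steps):
        np.matmul(m[:, s - 1], prefix[:, s - 1], out=prefix[:, s])
    suffix = np.empty_like(m)  # O_s = product of samples after s
    suffix[:, -1] = np.eye(4)
    for s in range(n_steps - 2, -1, -1):
        np.matmul(suffix[:, s + 1], m[:, s + 1], out=suffix[:, s])

    chain = m[:, -1] @ prefix[:, -1]
    # I_l = 0.25 va_l^T M vg_l
    z = chain @ VG_STATES.T  # (P, 4, 16)
    i_hat = 0.25 * np.einsum("la,pal->lp", VA_STATES, z)
    resid = i_hat - measured_flat  # (16, P)
    eps = float(np.sum(resid * resid))

    # W = sum_l 2 r_l va_l vg_l^T per pixel, with the 1/4 state factor
    w = 0.5 * np.einsum("lp,lab->pab", resid, _VAG_OUTER)

    dm_dtheta = voxel_mueller_dtheta(delta, theta, t_lr)
    dm_ddelta = voxel_mueller_ddelta(delta, theta, t_lr)

    # G_s = O_s^T W L_s^T for every sample, two batched matmuls
    wl = np.matmul(w[:, None], prefix.transpose(0, 1, 3, 2))
    g_mat = np.matmul(suffix.transpose(0, 1, 3, 2), wl)
    s_theta = np.sum(g_mat * dm_dtheta, axis=(-2, -1))
    s_delta = np.sum(g_mat * dm_ddelta, axis=(-2, -1))

    flat = arrs["flat"]
    valid = arrs["valid"]
    idx = flat[valid]
    np.add.at(
        gphi,
        idx,
        (
            s_theta * arrs["dtheta_dphi"] + s_delta * arrs["ddelta_dphi"]
        )[valid],
    )
    np.add.at(
        gpsi,
        idx,
        (
            s_theta * arrs["dtheta_dpsi"] + s_delta * arrs["ddelta_dpsi"]
        )[valid],
    )
    np.add.at(gne, idx, (s_delta * arrs["ddelta_dne"])[valid])
    return eps


def analytic_gradient(
    grid: VoxelGrid,
    measured: ProjectionSet,
    geometry: AcquisitionGeometry | None = None,
    forward: ForwardModel | None = None,
    projections: np.ndarray | None = None,
):
    """Analytic gradient of eps_I w.r.t. (phi, psi, n_e).

    Returns ``(eps_I, grad_phi, grad_psi, grad_n_e)`` with gradient arrays of
    the grid shape.  ``projections`` optionally restricts the sum to a subset
    of projection indices (mini-batching).
    """
    if forward is None:
        if geometry is None:
            geometry = AcquisitionGeometry(
                wavelength_um=measured.wavelength_um,
                voxel_size_um=measured.voxel_size_um,
                n_o=measured.n_o,
                angles=measured.angles,
            )
        forward = ForwardModel(grid.shape, geometry)
    n_vox = int(np.prod(grid.shape))
    gphi = np.zeros(n_vox)
    gpsi = np.zeros(n_vox)
    gne = np.zeros(n_vox)
    if projections is None:
        projections = np.arange(measured.n_projections)
    projections = np.asarray(projections, dtype=int)
    eps = 0.0
    n_pix = forward.n_pixels
    # chunk the batch to bound the memory of the per-step matrix caches
    max_rays = 20000
    chunk = max(1, max_rays // n_pix)
    for start in range(0, len(projections), chunk):
        sub = projections[start : start + chunk]
        meas = np.concatenate(
            [measured.intensities[i].reshape(-1, n_pix) for i in sub], axis=1
        )
        eps += _batch_gradient(forward, grid, meas, sub, gphi, gpsi, gne)
    shape = grid.shape
    return eps, gphi.reshape(shape), gpsi.reshape(shape), gne.reshape(shape)


# ---------------------------------------------------------------------------
# smoothing regularizers (6-neighbor pair sums)


def _director_derivatives(phi: np.ndarray, psi: np.ndarray):
    c = c_axis_vector(phi, psi)
    dphi = np.stack(
        [np.cos(phi) * np.cos(psi), np.cos(phi) * np.sin(psi), -np.sin(phi)],
        axis=-1,
    )
    dpsi = np.stack(
        [-np.sin(phi) * np.sin(psi), np.sin(phi) * np.cos(psi), np.zeros_like(phi)],
        axis=-1,
    )
    return c, dphi, dpsi


def smooth_reg_orientation(grid: VoxelGrid):
    """Director smoothness: sum over 6-neighbor pairs of 1 - (c_v . c_w)^2.

    Director-symmetric (invariant under any voxel's c -> -c); zero iff all
    neighboring c-axes are parallel or antiparallel.  Returns
    ``(value, grad_phi, grad_psi)``.
    """
    c, dphi, dpsi = _director_derivatives(grid.phi, grid.psi)
    value = 0.0
    gphi = np.zeros(grid.shape)
    gpsi = np.zeros(grid.shape)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sa, sb = tuple(sl_a), tuple(sl_b)
        dots = np.sum(c[sa] * c[sb], axis=-1)
        value += float(np.sum(1.0 - dots**2))
        # d/dx (1 - dot^2) = -2 dot * d(dot)/dx
        gphi[sa] += -2.0 * dots * np.sum(dphi[sa] * c[sb], axis=-1)
        gpsi[sa] += -2.0 * dots * np.sum(dpsi[sa] * c[sb], axis=-1)
        gphi[sb] += -2.0 * dots * np.sum(c[sa] * dphi[sb], axis=-1)
        gpsi[sb] += -2.0 * dots * np.sum(c[sa] * dpsi[sb], axis=-1)
    return value, gphi, gpsi


def smooth_reg_index(grid: VoxelGrid):
    """Index smoothness: sum over 6-neighbor pairs of (n_e,v - n_e,w)^2.

    Returns ``(value, grad_n_e)``; zero iff n_e is constant.
    """
    n = grid.n_e
    value = 0.0
    grad = np.zeros(grid.shape)
    for axis in range(3):
        diff = np.diff(n, axis=axis)
        value += float(np.sum(diff**2))
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        grad[tuple(sl_a)] += -2.0 * diff
        grad[tuple(sl_b)] += 2.0 * diff
    return value, grad


def n_neighbor_pairs(shape: tuple[int, int, int]) -> int:
    nx, ny, nz = shape
    return (nx - 1) * ny * nz + nx * (ny - 1) * nz + nx * ny * (nz - 1)


# ---------------------------------------------------------------------------
# Nesterov accelerated descent


def nesterov_step(
    x: np.ndarray,
    velocity: np.ndarray,
    grad_at_lookahead: np.ndarray,
    lr: float,
    momentum: float,
):
    """One Nesterov update.  The gradient must be evaluated at the
    look-ahead point ``x + momentum * velocity``.  With ``momentum = 0``
    this reduces to plain gradient descent ``x - lr * grad``.
    """
    if np.any(~np.isfinite(grad_at_lookahead)):
        raise FloatingPointError("non-finite gradient in Nesterov step")
    v_new = momentum * velocity - lr * grad_at_lookahead
    return x + v_new, v_new


def _wrap_angles(phi: np.ndarray, psi: np.ndarray):
    """Fold (phi, psi) back into [0, pi] x [0, 2 pi) (director chart)."""
    phi = np.mod(phi, 2.0 * np.pi)
    over = phi > np.pi
    phi = np.where(over, 2.0 * np.pi - phi, phi)
    psi = np.where(over, psi + np.pi, psi)
    return phi, np.mod(psi, 2.0 * np.pi)


def proximity_metrics(
    estimate: VoxelGrid,
    truth: VoxelGrid,
    support: np.ndarray | None = None,
    dn_max: float = 0.002,
):
    """(mean orientation proximity, mean normalized index error).

    Orientation proximity is the mean over voxels of ``|c_est . c_true|``
    (director-symmetric, 1 = perfect); the index error is the mean
    ``|n_e,est - n_e,true|`` normalized to the maximum birefringence.
    By default the metrics are evaluated over the sample support (voxels
    with non-zero true birefringence), or everywhere if the truth has none.
    """
    if estimate.shape != truth.shape:
        raise ValueError("grids have mismatched shapes")
    if support is None:
        support = np.abs(truth.birefringence) > 0
        if not np.any(support):
            support = np.ones(truth.shape, dtype=bool)
    ce = estimate.c_axis()[support]
    ct = truth.c_axis()[support]
    prox = float(np.mean(np.abs(np.sum(ce * ct, axis=-1))))
    err = float(np.mean(np.abs(estimate.n_e[support] - truth.n_e[support])) / dn_max)
    return prox, err


# ---------------------------------------------------------------------------
# absorption tomography (linear, decoupled)


def _system_matrix(fm: ForwardModel) -> scipy.sparse.csr_matrix:
    """Sparse ray-sampling operator: rows (projection, pixel), cols voxels;
    entries are path lengths in voxel units (constant 1 per sample)."""
    n_rays = fm.geometry.n_projections * fm.n_pixels
    flat = fm._flat_idx.reshape(n_rays, fm.n_steps)
    rows, steps = np.nonzero(flat >= 0)
    cols = flat[rows, steps]
    data = np.ones(len(rows))
    n_vox = int(np.prod(fm.shape))
    mat = scipy.sparse.coo_matrix(
        (data, (rows, cols)), shape=(n_rays, n_vox)
    )
    return mat.tocsr()


def transmission_images(measured: ProjectionSet) -> np.ndarray:
    """Isotropic transmission per pixel from the 16 polarization sets.

    Equals element (0, 0) of the synthesized Mueller matrix, i.e. the
    product of the per-voxel transmissions along the ray.
    """
    from .analysis import synthesize_mueller

    m = synthesize_mueller(measured.intensities)
    return m[..., 0, 0]


def reconstruct_absorption(
    measured: ProjectionSet,
    geometry: AcquisitionGeometry,
    shape: tuple[int, int, int],
    floor: float = 1e-6,
    damp: float = 0.1,
) -> np.ndarray:
    """Least-squares tomogram of the absorption coefficient A (per voxel).

    Solves ``sum_path A = -log(T)`` per ray with LSMR and clips the result
    at zero.  Transmission pixels at or below ``floor`` are clipped (with
    the standard Beer-Lambert caveat that they carry little information).
    """
    fm = ForwardModel(shape, geometry)
    trans = transmission_images(measured)
    trans = np.clip(trans, floor, None)
    b = -np.log(trans).reshape(-1)
    mat = _system_matrix(fm)
    sol = scipy.sparse.linalg.lsmr(mat, b, damp=damp, atol=1e-8, btol=1e-8)[0]
    return np.clip(sol, 0.0, None).reshape(shape)


# ---------------------------------------------------------------------------
# full reconstruction driver


def _random_init_grid(
    shape: tuple[int, int, int],
    config: ReconConfig,
    geometry: AcquisitionGeometry,
    rng: np.random.Generator,
) -> VoxelGrid:
    phi = rng.uniform(*config.init_phi_range, size=shape)
    psi = rng.uniform(*config.init_psi_range, size=shape)
    dn = rng.uniform(*config.init_dn_range, size=shape)
    return VoxelGrid(
        phi=phi,
        psi=psi,
        n_e=geometry.n_o + dn,
        absorption=np.zeros(shape),
        n_o=geometry.n_o,
        voxel_size_um=geometry.voxel_size_um,
        wavelength_um=geometry.wavelength_um,
    )


def reconstruct(
    measured: ProjectionSet,
    geometry: AcquisitionGeometry,
    config: ReconConfig,
    shape: tuple[int, int, int] | None = None,
    init: VoxelGrid | None = None,
    truth: VoxelGrid | None = None,
    verbose: bool = False,
) -> ReconState:
    """Stage-wise Nesterov reconstruction of (phi, psi, n_e) per voxel.

    The absorption tomogram is reconstructed first (linear tomography on
    -log transmission) and held fixed while the birefringence parameters
    are optimized.  Per-iteration traces of eps_I and both regularizers are
    recorded; if ``truth`` is given, orientation-proximity and normalized
    index-error traces are appended.
    """
    if shape is None:
        if init is not None:
            shape = init.shape
        else:
            nk, nj = measured.detector_shape
            shape = (nk, nj, nk)
    rng = np.random.default_rng(config.seed)
    grid = init.copy() if init is not None else _random_init_grid(
        shape, config, geometry, rng
    )
    if config.fit_absorption:
        grid.absorption = reconstruct_absorption(measured, geometry, shape)

    fm = ForwardModel(shape, geometry)
    n_data = measured.intensities.size
    n_pairs = max(n_neighbor_pairs(shape), 1)
    dn2 = config.dn_max**2

    v_phi = np.zeros(shape)
    v_psi = np.zeros(shape)
    v_ne = np.zeros(shape)
    lr_o = config.lr_orientation
    lr_n = config.lr_index
    traces: dict[str, list[float]] = {
        "eps_I": [], "reg_o": [], "reg_n": [], "objective": [],
    }
    if truth is not None:
        traces["orientation_proximity"] = []
        traces["index_error"] = []

    block = config.block_orientation + config.block_index
    best_obj = np.inf
    stall = 0
    ne_lo = geometry.n_o + config.dn_bounds[0]
    ne_hi = geometry.n_o + config.dn_bounds[1]

    n_proj = measured.n_projections
    for it in range(config.n_iterations):
        phase = it % block
        do_orient = phase < config.block_orientation
        if config.batch_projections and config.batch_projections < n_proj:
            batch = rng.choice(n_proj, config.batch_projections, replace=False)
            batch_scale = n_proj / config.batch_projections
        else:
            batch = None
            batch_scale = 1.0

        # look-ahead point for the active parameter group
        look = grid.copy()
        if do_orient:
            look.phi = grid.phi + config.momentum * v_phi
            look.psi = grid.psi + config.momentum * v_psi
        else:
            look.n_e = np.clip(
                grid.n_e + config.momentum * v_ne, ne_lo, ne_hi
            )

        eps, gphi, gpsi, gne = analytic_gradient(
            look, measured, forward=fm, projections=batch
        )
        eps *= batch_scale
        reg_o, rphi, rpsi = smooth_reg_orientation(look)
        reg_n, rne = smooth_reg_index(look)
        objective = (
            eps / n_data
            + config.weight_orientation * reg_o / n_pairs
            + config.weight_index * reg_n / (n_pairs * dn2)
        )
        if not np.isfinite(objective):
            raise FloatingPointError("non-finite loss during reconstruction")

        if do_orient:
            g1 = batch_scale * gphi / n_data + config.weight_orientation * rphi / n_pairs
            g2 = batch_scale * gpsi / n_data + config.weight_orientation * rpsi / n_pairs
            grid.phi, v_phi = nesterov_step(grid.phi, v_phi, g1, lr_o, config.momentum)
            grid.psi, v_psi = nesterov_step(grid.psi, v_psi, g2, lr_o, config.momentum)
            grid.phi, grid.psi = _wrap_angles(grid.phi, grid.psi)
        else:
            g3 = batch_scale * gne / n_data + config.weight_index * rne / (n_pairs * dn2)
            new_ne, v_ne = nesterov_step(grid.n_e, v_ne, g3, lr_n, config.momentum)
            grid.n_e = np.clip(new_ne, ne_lo, ne_hi)

        traces["eps_I"].append(eps)
        traces["reg_o"].append(reg_o)
        traces["reg_n"].append(reg_n)
        traces["objective"].append(objective)
        if truth is not None:
            prox, ierr = proximity_metrics(grid, truth, dn_max=config.dn_max)
            traces["orientation_proximity"].append(prox)
            traces["index_error"].append(ierr)
        if verbose:
            print(
                f"iter {it:4d}  eps_I={eps:.6g}  reg_o={reg_o:.4g}  "
                f"reg_n={reg_n:.4g}  obj={objective:.6g}"
            )

        # divergence back-off: objective not improving over a patience window
        if objective < best_obj * (1.0 - config.plateau_rtol):
            best_obj = objective
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                lr_o *= config.lr_backoff
                lr_n *= config.lr_backoff
                v_phi[:] = 0.0
                v_psi[:] = 0.0
                v_ne[:] = 0.0
                stall = 0
                if verbose:
                    print(f"iter {it:4d}  learning-rate back-off -> {lr_o:.3g}")

    traces_arr = {k: np.asarray(v) for k, v in traces.items()}
    return ReconState(
        grid=grid,
        traces=traces_arr,
        momentum={"phi": v_phi, "psi": v_psi, "n_e": v_ne},
        config=config,
    )


def reconstruct_multistart(
    measured: ProjectionSet,
    geometry: AcquisitionGeometry,
    config: ReconConfig,
    n_starts: int = 3,
    shape: tuple[int, int, int] | None = None,
    truth: VoxelGrid | None = None,
) -> ReconState:
    """Run :func:`reconstruct` from several random initializations and keep
    the run with the lowest final objective.

    The intensity-fit problem is non-convex; on small dense volumes a single
    random start can be trapped in a local minimum, and restarting with a
    different initialization is the standard remedy.  Start ``k`` uses seed
    ``config.seed + k``.
    """
    best: ReconState | None = None
    for k in range(n_starts):
        cfg_k = replace(config, seed=config.seed + k)
        state = reconstruct(measured, geometry, cfg_k, shape=shape, truth=truth)
        if best is None or (
            state.traces["objective"][-1] < best.traces["objective"][-1]
        ):
            best = state
    assert best is not None
    return best
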