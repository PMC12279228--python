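"""Uniaxial crystal optics for a single birefringent voxel.

Every voxel of the tomogram is modelled as a uniaxial index ellipsoid with
ordinary index ``n_o`` (a global constant, matched to the immersion liquid),
extraordinary index ``n_e`` and an optic axis (c-axis) given by polar and
azimuthal angles ``(phi, psi)`` in the object frame ``(x, y, z)``::

    c = (sin(phi) cos(psi), sin(phi) sin(psi), cos(phi))

The c-axis is a headless director: ``c`` and ``-c`` describe the same
ellipsoid, and all functions in this module are invariant under
``(phi, psi) -> (pi - phi, psi + pi)``.

Light propagates along the lab axis ``p`` and is measured in the transverse
plane spanned by ``(k, j)``.  The sample is rotated into the beam by the
tomographic operator ``R_s = R_k(beta) R_j(alpha)`` (right-handed rotations
about the lab ``k`` and ``j`` axes).  For a ray crossing one voxel the
accumulated effect is that of a linear retarder with retardance

    delta = 2 pi d (n_E - n_o) / lambda

where ``n_E`` is the incidence-dependent e-wave index and ``d`` the path
length through the voxel, plus a scalar transmission ``t_LR``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "POL_STATES",
    "rotation_about_j",
    "rotation_about_k",
    "sample_rotation",
    "c_axis_vector",
    "e_wave_index",
    "angle_to_c_axis",
    "fast_axis_angle",
    "retarder_params",
    "voxel_mueller",
    "rotator_mueller",
    "retarder_mueller_unrotated",
    "pol_state_mueller",
    "pol_state_stokes",
]

# Poincare-sphere coordinates (s1, s2, s3) of the four probing states:
# two circular (poles) and two linear (equator at 0 and 45 degrees).
POL_STATES: dict[str, tuple[float, float, float]] = {
    "RCP": (0.0, 0.0, 1.0),
    "LCP": (0.0, 0.0, -1.0),
    "LP0": (1.0, 0.0, 0.0),
    "LP45": (0.0, 1.0, 0.0),
}

# Canonical ordering of the 16 generator/analyzer combinations.
POL_STATE_ORDER = ("RCP", "LCP", "LP0", "LP45")


def rotation_about_j(alpha: float) -> np.ndarray:
    """Right-handed rotation by ``alpha`` about the lab j-axis (axis 1)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    return np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])


def rotation_about_k(beta: float) -> np.ndarray:
    """Right-handed rotation by ``beta`` about the lab k-axis (axis 0)."""
    cb, sb = np.cos(beta), np.sin(beta)
    return np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])


def sample_rotation(alpha: float, beta: float) -> np.ndarray:
    """Tomographic rotation ``R_s = R_k(beta) R_j(alpha)``.

    Maps object-frame vectors into the lab frame ``(k, j, p)`` where
    ``k = (1, 0, 0)``, ``j = (0, 1, 0)`` and the beam axis ``p = (0, 0, 1)``.
    """
    return rotation_about_k(beta) @ rotation_about_j(alpha)


def c_axis_vector(phi, psi) -> np.ndarray:
    """Unit c-axis director from polar/azimuthal angles; broadcasts."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    sp = np.sin(phi)
    return np.stack(
        [sp * np.cos(psi), sp * np.sin(psi), np.cos(phi)], axis=-1
    )


def _check_unit(c: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if not np.allclose(np.linalg.norm(c, axis=-1), 1.0, atol=tol):
        raise ValueError("c-axis vector must have unit norm")
    return c


def e_wave_index(n_o: float, n_e: float, phi_angle) -> np.ndarray | float:
    """Effective e-wave index for a ray at angle ``phi_angle`` to the c-axis.

        n_E = n_o n_e / sqrt(n_o^2 sin^2(phi) + n_e^2 cos^2(phi))

    Along the c-axis (``phi = 0``) no double refraction occurs and
    ``n_E = n_o``; perpendicular to it ``n_E = n_e``.
    """
    if n_o <= 0 or np.any(np.asarray(n_e) <= 0):
        raise ValueError("refractive indices must be positive")
    phi_angle = np.asarray(phi_angle, dtype=float)
    s2 = np.sin(phi_angle) ** 2
    c2 = np.cos(phi_angle) ** 2
    out = n_o * n_e / np.sqrt(n_o**2 * s2 + n_e**2 * c2)
    return float(out) if out.ndim == 0 else out


def angle_to_c_axis(c, alpha: float, beta: float) -> float:
    """Angle ``phi = arccos(p . R_s c)`` between the beam and the c-axis."""
    c = _check_unit(c)
    g = sample_rotation(alpha, beta) @ c
    return float(np.arccos(np.clip(g[2], -1.0, 1.0)))


def fast_axis_angle(c, alpha: float, beta: float, *, eps: float = 1e-12):
    """In-plane fast-axis angle of the rotated c-axis, in ``[0, pi)``.

    The rotated c-axis is projected onto the transverse ``(k, j)`` plane and
    the angle from ``k`` is taken with a two-argument arctangent (the
    projection is implicitly renormalized), then folded modulo pi.

    Returns ``(theta, degenerate)``: when the c-axis is parallel to the beam
    the projection vanishes, theta is physically irrelevant (the retardance
    is zero there) and the conventional value 0 is returned with
    ``degenerate=True``.
    """
    c = _check_unit(c)
    g = sample_rotation(alpha, beta) @ c
    rho2 = g[0] ** 2 + g[1] ** 2
    if rho2 < eps:
        return 0.0, True
    theta = np.arctan2(g[1], g[0]) % np.pi
    return float(theta), False


def retarder_params(
    phi: float,
    psi: float,
    n_e: float,
    *,
    n_o: float,
    wavelength: float,
    path_length: float,
    absorption: float = 0.0,
):
    """Retarder parameters ``(delta, theta, t_LR)`` of one voxel at normal
    tomographic incidence ``(alpha, beta) = (0, 0)`` is a special case of the
    general helper used by the forward model; kept scalar for clarity.

    ``absorption`` is the attenuation coefficient per unit ``path_length``;
    the transmission follows Beer-Lambert, ``t_LR = exp(-absorption)`` for a
    path of one voxel.
    """
    c = c_axis_vector(phi, psi)
    phi_angle = angle_to_c_axis(c, 0.0, 0.0)
    n_E = e_wave_index(n_o, n_e, phi_angle)
    delta = 2.0 * np.pi * path_length * (n_E - n_o) / wavelength
    theta, _ = fast_axis_angle(c, 0.0, 0.0)
    t_lr = float(np.exp(-absorption))
    return delta, theta, t_lr


def rotator_mueller(theta: float) -> np.ndarray:
    """Mueller matrix of an optical rotator by ``theta`` (acts via 2*theta)."""
    c2, s2 = np.cos(2.0 * theta), np.sin(2.0 * theta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c2, s2, 0.0],
            [0.0, -s2, c2, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def retarder_mueller_unrotated(delta: float) -> np.ndarray:
    """Mueller matrix of a linear retarder with fast axis along k."""
    cd, sd = np.cos(delta), np.sin(delta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, cd, sd],
            [0.0, 0.0, -sd, cd],
        ]
    )


def voxel_mueller(delta, theta, t_lr=1.0) -> np.ndarray:
    """Mueller matrix of a linearly birefringent voxel (closed form).

    Equals ``t_lr * R(-theta) @ LR0(delta) @ R(theta)`` with the rotator and
    unrotated-retarder factors above.  Broadcasts over array inputs; the
    trailing two axes of the result are the 4x4 matrix.
    """
    delta = np.asarray(delta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    t_lr = np.asarray(t_lr, dtype=float)
    if np.any(~np.isfinite(delta)) or np.any(~np.isfinite(theta)):
        raise ValueError("retarder parameters must be finite")
    if np.any(t_lr < 0) or np.any(t_lr > 1):
        raise ValueError("transmission t_LR must lie in [0, 1]")
    shape = np.broadcast_shapes(delta.shape, theta.shape, t_lr.shape)
    c2 = np.cos(2.0 * theta)
    s2 = np.sin(2.0 * theta)
    cd = np.cos(delta)
    sd = np.sin(delta)
    m = np.zeros(shape + (4, 4))
    m[..., 0, 0] = 1.0
    m[..., 1, 1] = c2**2 + cd * s2**2
    m[..., 1, 2] = (1.0 - cd) * c2 * s2
    m[..., 1, 3] = -sd * s2
    m[..., 2, 1] = (1.0 - cd) * c2 * s2
    m[..., 2, 2] = cd * c2**2 + s2**2
    m[..., 2, 3] = c2 * sd
    m[..., 3, 1] = sd * s2
    m[..., 3, 2] = -c2 * sd
    m[..., 3, 3] = cd
    return t_lr[..., None, None] * m


def voxel_mueller_dtheta(delta, theta, t_lr=1.0) -> np.ndarray:
    """Element-wise derivative of :func:`voxel_mueller` w.r.t. ``theta``."""
    delta = np.asarray(delta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    t_lr = np.asarray(t_lr, dtype=float)
    shape = np.broadcast_shapes(delta.shape, theta.shape, t_lr.shape)
    c2 = np.cos(2.0 * theta)
    s2 = np.sin(2.0 * theta)
    cd = np.cos(delta)
    sd = np.sin(delta)
    m = np.zeros(shape + (4, 4))
    cs = c2 * s2
    m[..., 1, 1] = -4.0 * cs * (1.0 - cd)
    m[..., 1, 2] = 2.0 * (1.0 - cd) * (c2**2 - s2**2)
    m[..., 1, 3] = -2.0 * sd * c2
    m[..., 2, 1] = m[..., 1, 2]
    m[..., 2, 2] = 4.0 * cs * (1.0 - cd)
    m[..., 2, 3] = -2.0 * s2 * sd
    m[..., 3, 1] = 2.0 * sd * c2
    m[..., 3, 2] = 2.0 * s2 * sd
    return t_lr[..., None, None] * m


def voxel_mueller_ddelta(delta, theta, t_lr=1.0) -> np.ndarray:
    """Element-wise derivative of :func:`voxel_mueller` w.r.t. ``delta``."""
    delta = np.asarray(delta, dtype=float)
    theta = np.asarray(theta, dtype=float)
    t_lr = np.asarray(t_lr, dtype=float)
    shape = np.broadcast_shapes(delta.shape, theta.shape, t_lr.shape)
    c2 = np.cos(2.0 * theta)
    s2 = np.sin(2.0 * theta)
    cd = np.cos(delta)
    sd = np.sin(delta)
    m = np.zeros(shape + (4, 4))
    m[..., 1, 1] = -sd * s2**2
    m[..., 1, 2] = sd * c2 * s2
    m[..., 1, 3] = -cd * s2
    m[..., 2, 1] = m[..., 1, 2]
    m[..., 2, 2] = -sd * c2**2
    m[..., 2, 3] = c2 * cd
    m[..., 3, 1] = cd * s2
    m[..., 3, 2] = -c2 * cd
    m[..., 3, 3] = -sd
    return t_lr[..., None, None] * m


def pol_state_stokes(state: str) -> np.ndarray:
    """Fully polarized unit-intensity Stokes vector of a named state."""
    if state not in POL_STATES:
        raise ValueError(f"unknown polarization state {state!r}")
    s1, s2, s3 = POL_STATES[state]
    return np.array([1.0, s1, s2, s3])


def pol_state_mueller(state: str, role: str = "generator") -> np.ndarray:
    """Mueller matrix of an ideal polarizer preparing/projecting ``state``.

    For a state with Poincare coordinates ``s`` the ideal element is
    ``0.5 * outer(v, v)`` with ``v = (1, s1, s2, s3)``; the same matrix
    serves as generator (PSG) and analyzer (PSA).  Applied to unpolarized
    light ``S = (1, 0, 0, 0)`` the generator emits ``0.5 * v``; a matched
    generator/analyzer pair with an identity sample therefore transmits the
    co-polarized maximum intensity of 0.5, to which simulated images are
    conventionally normalized.
    """
    if role not in ("generator", "analyzer"):
        raise ValueError(f"unknown role {role!r}")
    v = pol_state_stokes(state)
    return 0.5 * np.outer(v, v)


def copolarized_max() -> float:
    """Intensity through matched PSG/PSA with an identity sample (S0 = 1)."""
    return 0.5
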