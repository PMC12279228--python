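"""Mueller-matrix data reduction for projection images.

From the 16 polarization-resolved intensities of a pixel the full 4x4
Mueller matrix is synthesized by inverting the generator/analyzer state
matrices.  For samples that act (approximately) as a cumulative linear
retarder, the total retardance delta_tot, fast-axis angle theta_tot and the
isotropic transmission are then extracted from the retarder element pattern,
which is the conventional reduction shown as tick maps in polarized-light
microscopy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .forward import VA_STATES, VG_STATES
from .geometry import N_POL_SETS

__all__ = [
    "RetardanceMap",
    "synthesize_mueller",
    "extract_retarder",
    "extract_retardance_map",
    "tickmap_export",
]


def _state_matrices() -> tuple[np.ndarray, np.ndarray]:
    """Analyzer (rows) and generator (columns) Stokes state matrices.

    ``I16[a, g] = (A @ M @ G)[a, g]`` with the factor-1/2 ideal-polarizer
    convention; both are invertible for the RCP/LCP/LP0/LP45 state set
    (asserted at import time).
    """
    a_mat = 0.5 * VA_STATES[::4, :]  # analyzer states repeat every 4 sets
    g_mat = 0.5 * VG_STATES[:4, :].T
    return a_mat, g_mat


_A_MAT, _G_MAT = _state_matrices()
_A_INV = np.linalg.inv(_A_MAT)
_G_INV = np.linalg.inv(_G_MAT)
assert np.linalg.cond(_A_MAT) < 1e3 and np.linalg.cond(_G_MAT) < 1e3


def synthesize_mueller(intensities: np.ndarray) -> np.ndarray:
    """Per-pixel Mueller matrix from 16 polarization-set intensities.

    ``intensities`` may be any array with the 16 polarization sets on one
    axis laid out as ``analyzer-major`` (set l = 4*a + g, the storage order
    of :class:`~muellertomo.forward.ProjectionSet`): shape ``(..., 16)`` or
    the projection-stack layout ``(..., 16, nk, nj)``.  Returns matrices of
    shape ``(..., [nk, nj,] 4, 4)``.  The synthesis is linear: scaling all
    16 intensities by s scales the matrix by s; it inverts the intensity
    simulation exactly for noiseless data.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim >= 3 and arr.shape[-3] == N_POL_SETS:
        arr = np.moveaxis(arr, -3, -1)  # (..., nk, nj, 16)
    if arr.shape[-1] != N_POL_SETS:
        raise ValueError("expected 16 polarization sets on one axis")
    i16 = arr.reshape(arr.shape[:-1] + (4, 4))
    return _A_INV @ i16 @ _G_INV


def extract_retarder(m: np.ndarray, tol: float = 1e-3):
    """Nearest-retarder parameters ``(delta_tot, theta_tot, transmission)``.

    Interprets ``m`` (shape ``(..., 4, 4)``) through the linear-retarder
    element pattern: transmission is element (0, 0); the retardance is taken
    on its principal branch [0, pi] from the (3, 3) element with the sign
    quadrant fixed by the sin-delta elements; the fast axis comes from a
    two-argument arctangent over the 2-theta-bearing elements, folded into
    [0, pi).  Also returns a boolean ``flagged`` array marking pixels whose
    normalized lower 3x3 block is not orthogonal within ``sqrt(tol)``
    (cumulative matrices of thick heterogeneous samples are generally not
    pure retarders).
    """
    m = np.asarray(m, dtype=float)
    t = m[..., 0, 0]
    t_safe = np.where(np.abs(t) < 1e-30, 1.0, t)
    mn = m / t_safe[..., None, None]
    cos_d = np.clip(mn[..., 3, 3], -1.0, 1.0)
    sin_d = np.hypot(mn[..., 3, 1], mn[..., 3, 2])
    delta = np.arctan2(sin_d, cos_d)
    degenerate = sin_d < 1e-12
    theta = np.where(
        degenerate,
        0.0,
        np.mod(0.5 * np.arctan2(mn[..., 3, 1], -mn[..., 3, 2]), np.pi),
    )
    block = mn[..., 1:, 1:]
    gram = block @ np.swapaxes(block, -1, -2)
    resid = np.linalg.norm(gram - np.eye(3), axis=(-2, -1))
    flagged = resid > np.sqrt(tol)
    return delta, theta, t, flagged


@dataclass
class RetardanceMap:
    """Cumulative retardance / fast-axis / transmission images."""

    delta_tot: np.ndarray
    theta_tot: np.ndarray
    transmission: np.ndarray
    flagged: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(np.shape(self.delta_tot), dtype=bool)


def extract_retardance_map(intensities: np.ndarray, tol: float = 1e-3) -> RetardanceMap:
    """16 polarization images -> cumulative retarder maps for one projection."""
    m = synthesize_mueller(intensities)
    delta, theta, t, flagged = extract_retarder(m, tol=tol)
    return RetardanceMap(delta, theta, t, flagged)


def tickmap_export(
    rmap: RetardanceMap,
    path: str,
    downsample: int = 1,
    png_path: str | None = None,
) -> None:
    """Write a fast-axis tick map: CSV (k, j, theta, delta, transmission),
    optionally rendered to PNG with tick direction = theta_tot and tick
    length/color proportional to delta_tot."""
    delta = rmap.delta_tot[::downsample, ::downsample]
    theta = rmap.theta_tot[::downsample, ::downsample]
    trans = rmap.transmission[::downsample, ::downsample]
    nk, nj = delta.shape
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["k", "j", "theta", "delta", "transmission"])
        for k in range(nk):
            for j in range(nj):
                writer.writerow(
                    [
                        k * downsample,
                        j * downsample,
                        f"{theta[k, j]:.8g}",
                        f"{delta[k, j]:.8g}",
                        f"{trans[k, j]:.8g}",
                    ]
                )
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        kk, jj = np.meshgrid(np.arange(nk), np.arange(nj), indexing="ij")
        u = delta * np.cos(theta)
        v = delta * np.sin(theta)
        fig, ax = plt.subplots(figsize=(6, 6 * nj / max(nk, 1)))
        ax.imshow(trans.T, origin="lower", cmap="gray")
        ax.quiver(
            kk, jj, u, v, delta,
            angles="xy", pivot="middle", headlength=0, headwidth=1,
            headaxislength=0, cmap="viridis",
        )
        ax.set_xlabel("k")
        ax.set_ylabel("j")
        fig.savefig(png_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
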