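"""HDF5 / YAML / TIFF plumbing.

Projection stacks and tomograms are stored as self-describing HDF5:

* projections: ``/intensities[i, l, k, j]``, ``/angles[i, 2]`` (degrees)
  plus metadata attributes (wavelength, voxel size, n_o, full well, seed).
* tomograms: ``/phi``, ``/psi``, ``/n_e``, ``/absorption`` volumes plus the
  same geometry metadata; optional ``/traces/<name>`` loss curves.

Angles are degrees on disk and radians in memory.
"""

from __future__ import annotations

import csv

import h5py
import numpy as np
import yaml

from .forward import ProjectionSet
from .geometry import AcquisitionGeometry
from .grid import VoxelGrid

__all__ = [
    "save_projections",
    "load_projections",
    "save_tomogram",
    "load_tomogram",
    "save_traces_csv",
    "load_config",
    "export_tiff_stack",
]


def _write_meta(h5obj, **meta) -> None:
    for key, val in meta.items():
        if val is not None:
            h5obj.attrs[key] = val


def save_projections(path: str, projections: ProjectionSet, **meta) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("intensities", data=projections.intensities)
        fh.create_dataset("angles", data=np.rad2deg(projections.angles))
        _write_meta(
            fh,
            wavelength_um=projections.wavelength_um,
            voxel_size_um=projections.voxel_size_um,
            n_o=projections.n_o,
            **projections.meta,
            **meta,
        )


def load_projections(path: str) -> ProjectionSet:
    with h5py.File(path, "r") as fh:
        intensities = fh["intensities"][()]
        angles = np.deg2rad(fh["angles"][()])
        attrs = dict(fh.attrs)
    return ProjectionSet(
        intensities=intensities,
        angles=angles,
        wavelength_um=float(attrs.pop("wavelength_um", 0.625)),
        voxel_size_um=float(attrs.pop("voxel_size_um", 23.44)),
        n_o=float(attrs.pop("n_o", 1.48)),
        meta=attrs,
    )


def geometry_from_projections(projections: ProjectionSet) -> AcquisitionGeometry:
    return AcquisitionGeometry(
        wavelength_um=projections.wavelength_um,
        voxel_size_um=projections.voxel_size_um,
        n_o=projections.n_o,
        angles=projections.angles,
    )


def save_tomogram(
    path: str, grid: VoxelGrid, traces: dict | None = None, **meta
) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("phi", data=grid.phi)
        fh.create_dataset("psi", data=grid.psi)
        fh.create_dataset("n_e", data=grid.n_e)
        fh.create_dataset("absorption", data=grid.absorption)
        _write_meta(
            fh,
            n_o=grid.n_o,
            voxel_size_um=grid.voxel_size_um,
            wavelength_um=grid.wavelength_um,
            **meta,
        )
        if traces:
            grp = fh.create_group("traces")
            for name, arr in traces.items():
                grp.create_dataset(name, data=np.asarray(arr))


def load_tomogram(path: str) -> tuple[VoxelGrid, dict]:
    with h5py.File(path, "r") as fh:
        grid = VoxelGrid(
            phi=fh["phi"][()],
            psi=fh["psi"][()],
            n_e=fh["n_e"][()],
            absorption=fh["absorption"][()],
            n_o=float(fh.attrs.get("n_o", 1.48)),
            voxel_size_um=float(fh.attrs.get("voxel_size_um", 23.44)),
            wavelength_um=float(fh.attrs.get("wavelength_um", 0.625)),
        )
        traces = {}
        if "traces" in fh:
            traces = {k: fh["traces"][k][()] for k in fh["traces"]}
    return grid, traces


def save_traces_csv(path: str, traces: dict) -> None:
    """Per-iteration loss/regularizer/proximity traces as CSV columns."""
    names = list(traces)
    arrays = [np.asarray(traces[n]) for n in names]
    n_rows = max((len(a) for a in arrays), default=0)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration"] + names)
        for i in range(n_rows):
            writer.writerow(
                [i] + [f"{a[i]:.10g}" if i < len(a) else "" for a in arrays]
            )


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg


def export_tiff_stack(path: str, projections: ProjectionSet) -> None:
    """Projection stack as a multipage 32-bit TIFF (for visual inspection)."""
    import tifffile

    n_proj, n_pol, nk, nj = projections.intensities.shape
    tifffile.imwrite(
        path,
        projections.intensities.reshape(n_proj * n_pol, nk, nj).astype(np.float32),
    )
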