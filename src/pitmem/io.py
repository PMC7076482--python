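"""Export helpers: legacy-ASCII VTK, HDF5 and tabular writers.

The VTK writers emit the legacy ASCII format (STRUCTURED_POINTS for voxel
fields, POLYDATA lines for beam networks), which every VTK-based viewer
reads without extra dependencies.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np

from .voxel import VoxelGrid

__all__ = [
    "write_vtk_image",
    "write_vtk_beams",
    "write_hdf5_fields",
]


def write_vtk_image(
    path,
    grid: VoxelGrid,
    cell_scalars: Optional[Dict[str, np.ndarray]] = None,
    cell_vectors: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write voxel cell data as legacy VTK STRUCTURED_POINTS (ASCII).

    Scalars/vectors must have the grid's (nx, ny, nz) leading shape; the
    mask itself is always written as scalar field ``solid``.
    """
    nx, ny, nz = grid.shape
    h = grid.voxel_size
    scalars = {"solid": grid.mask.astype(np.int8)}
    scalars.update(cell_scalars or {})
    vectors = cell_vectors or {}
    lines = [
        "# vtk DataFile Version 3.0",
        "pitmem voxel field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
        f"SPACING {h} {h} {h}",
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, arr in scalars.items():
        arr = np.asarray(arr)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest: transpose to (z, y, x) then ravel
        lines.append(" ".join(map(str, arr.transpose(2, 1, 0).ravel())))
    for name, arr in vectors.items():
        arr = np.asarray(arr)
        lines.append(f"VECTORS {name} float")
        flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
        lines.append("\n".join(" ".join(map(str, row)) for row in flat))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_beams(path, nodes: np.ndarray, elements, point_scalars=None) -> None:
    """Write a beam network as legacy VTK POLYDATA lines with point data."""
    nodes = np.asarray(nodes, dtype=float)
    lines = [
        "# vtk DataFile Version 3.0",
        "pitmem beam network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(nodes)} float",
    ]
    lines.extend(" ".join(map(str, p)) for p in nodes)
    elems = [(a, b) for a, b, *_ in elements]
    lines.append(f"LINES {len(elems)} {3 * len(elems)}")
    lines.extend(f"2 {a} {b}" for a, b in elems)
    if point_scalars:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_scalars.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.append(" ".join(map(str, np.asarray(arr).ravel())))
    Path(path).write_text("\n".join(lines) + "\n")


def write_hdf5_fields(path, grid: VoxelGrid, **fields) -> None:
    """Store the mask plus any named arrays (e.g. the distance field) in HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["voxel_size_nm"] = grid.voxel_size
        f.create_dataset("solid", data=grid.mask, compression="gzip")
        for name, arr in fields.items():
            f.create_dataset(name, data=np.asarray(arr), compression="gzip")
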