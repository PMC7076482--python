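"""Analytic voxel geometries used as solver oracles.

Each fixture is an exact voxel mask of a geometry with a known closed-form
or easily reasoned flow/pore answer: a plane slit, a cylindrical tube, a
periodic square array of transverse cylinders, a sealed cavity next to an
open channel, and a pair of identical channels.  All dimensions in nm.
"""

from __future__ import annotations

import numpy as np

from .voxel import VoxelGrid

__all__ = ["fixture_geometry"]


def fixture_geometry(name: str, voxel_size: float, **params) -> VoxelGrid:
    """Build a named analytic fixture geometry.

    Names: ``slit``, ``tube``, ``cylinder_array``, ``sealed_cavity``,
    ``twin_channel``.  See the individual builders for their parameters.
    """
    builders = {
        "slit": _slit,
        "tube": _tube,
        "cylinder_array": _cylinder_array,
        "sealed_cavity": _sealed_cavity,
        "twin_channel": _twin_channel,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(builders)}")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    return builders[name](voxel_size, **params)


def _centers(n: int, h: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * h


def _slit(h: float, gap: float = 50.0, width: float = 100.0, length: float = 100.0) -> VoxelGrid:
    """Plane slit: fluid slab of round(gap/h) voxel layers across x.

    Flow runs along z between two parallel walls; y is invariant.
    """
    if min(gap, width, length) <= 0:
        raise ValueError("dimensions must be positive")
    nx = max(1, int(round(width / h)))
    ny = max(1, int(round(min(width, 5 * h) / h)))
    nz = max(1, int(round(length / h)))
    m = int(round(gap / h))
    if m < 1 or m > nx:
        raise ValueError("gap must fit inside the tile")
    mask = np.ones((nx, ny, nz), dtype=bool)
    i0 = (nx - m) // 2
    mask[i0 : i0 + m, :, :] = False
    return VoxelGrid(mask, h)


def _tube(h: float, radius: float = 30.0, width: float = 100.0, length: float = 100.0) -> VoxelGrid:
    """Cylindrical through-hole of given radius along z in a solid tile."""
    if min(radius, width, length) <= 0:
        raise ValueError("dimensions must be positive")
    nx = ny = max(1, int(round(width / h)))
    nz = max(1, int(round(length / h)))
    x = _centers(nx, h) - width / 2
    y = _centers(ny, h) - width / 2
    X, Y = np.meshgrid(x, y, indexing="ij")
    hole = X**2 + Y**2 <= radius**2
    mask = np.ones((nx, ny, nz), dtype=bool)
    mask[hole, :] = False
    return VoxelGrid(mask, h)


def _cylinder_array(
    h: float,
    radius: float = 20.0,
    spacing: float = 64.0,
    n_rows: int = 4,
    depth: float = 10.0,
) -> VoxelGrid:
    """Periodic square array of solid cylinders transverse to the flow.

    Cylinder axes run along y; the flow (z) crosses ``n_rows`` rows spaced
    ``spacing`` apart, one cylinder per lateral period (x).  With periodic
    lateral boundaries this is an infinite square array.
    """
    if min(radius, spacing, depth) <= 0 or n_rows < 1:
        raise ValueError("dimensions must be positive")
    nx = max(1, int(round(spacing / h)))
    ny = max(1, int(round(depth / h)))
    nz = n_rows * nx
    x = _centers(nx, h)
    z = _centers(nz, h)
    X, Z = np.meshgrid(x, z, indexing="ij")
    solid2d = np.zeros((nx, nz), dtype=bool)
    for row in range(n_rows):
        cx = spacing / 2
        cz = (row + 0.5) * spacing
        solid2d |= (X - cx) ** 2 + (Z - cz) ** 2 <= radius**2
        # periodic images across the lateral wrap
        solid2d |= (X - cx - spacing) ** 2 + (Z - cz) ** 2 <= radius**2
        solid2d |= (X - cx + spacing) ** 2 + (Z - cz) ** 2 <= radius**2
    mask = np.repeat(solid2d[:, None, :], ny, axis=1)
    return VoxelGrid(mask, h)


def _sealed_cavity(
    h: float,
    channel_radius: float = 15.0,
    cavity_diameter: float = 60.0,
    width: float = 200.0,
    length: float = 120.0,
) -> VoxelGrid:
    """An open cylindrical channel beside a fully sealed spherical cavity.

    The cavity is larger than the channel yet carries no flow: the fixture
    for the obstructed-pore cases.
    """
    if min(channel_radius, cavity_diameter, width, length) <= 0:
        raise ValueError("dimensions must be positive")
    nx = ny = max(1, int(round(width / h)))
    nz = max(1, int(round(length / h)))
    xs = _centers(nx, h)
    ys = _centers(ny, h)
    zs = _centers(nz, h)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    mask = np.ones((nx, ny, nz), dtype=bool)
    # channel at a quarter of the tile
    cx, cy = width / 4, width / 2
    mask[(X - cx) ** 2 + (Y - cy) ** 2 <= channel_radius**2] = False
    # sealed sphere at three quarters
    sx, sy, sz = 3 * width / 4, width / 2, length / 2
    R = cavity_diameter / 2
    mask[(X - sx) ** 2 + (Y - sy) ** 2 + (Z - sz) ** 2 <= R**2] = False
    return VoxelGrid(mask, h)


def _twin_channel(
    h: float,
    radius: float = 15.0,
    width: float = 200.0,
    length: float = 100.0,
) -> VoxelGrid:
    """Two identical parallel cylindrical channels through the tile."""
    if min(radius, width, length) <= 0:
        raise ValueError("dimensions must be positive")
    nx = ny = max(1, int(round(width / h)))
    nz = max(1, int(round(length / h)))
    xs = _centers(nx, h)
    ys = _centers(ny, h)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    mask2d = np.ones((nx, ny), dtype=bool)
    for cx in (width / 4, 3 * width / 4):
        mask2d[(X - cx) ** 2 + (Y - width / 2) ** 2 <= radius**2] = False
    mask = np.repeat(mask2d[:, :, None], nz, axis=2)
    return VoxelGrid(mask, h)
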