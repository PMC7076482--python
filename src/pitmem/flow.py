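"""Steady creeping flow through a voxelised membrane.

Solves the Stokes equations  grad p = mu * laplacian(V),  div V = 0  on the
fluid phase of a :class:`~pitmem.voxel.VoxelGrid` with a prescribed pressure
drop between the two z-faces, no-slip on every solid surface and periodic
(or free-slip wall) lateral boundaries.  The discretisation is a staggered
marker-and-cell finite-volume scheme: velocities live on cell faces,
pressures at cell centres, so discrete mass conservation is exact up to the
linear-solver tolerance.  The symmetric saddle-point system is solved with
MINRES under diagonal preconditioning; the pressure block is precondition-
free because the MAC Schur complement is spectrally close to the identity
once the equations are scaled to voxel units.

Walls are honoured to second order: a tangential velocity sample whose
neighbouring sample sits inside solid uses a mirror ghost value, which
places the no-slip plane exactly on the voxel face.

Geometry arrives in nm; everything internal is converted to SI.  Reported
velocities are m/s, pressures Pa, permeability m^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, minres

from .voxel import VoxelGrid

__all__ = [
    "FluidProps",
    "FlowField",
    "FlowSummary",
    "solve_stokes",
    "summarize_flow",
    "per_pore_flux",
]

NM = 1e-9


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid: defaults are water at 20 degrees C."""

    density: float = 998.0  # kg/m^3
    viscosity: float = 1e-3  # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass
class FlowField:
    """Discrete MAC velocity/pressure solution.

    ``u``/``v`` have one sample per cell on the face to the cell's -x/-y
    side (periodic wrap), ``w`` has nz+1 z-face layers.  Velocities are m/s,
    pressure Pa (NaN on solid cells).
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    pressure: np.ndarray
    dp: float
    grid: VoxelGrid
    fluid: FluidProps
    percolating: bool
    residual: float
    fluid_mask: np.ndarray  # cells actually solved (connected to a z-face)

    def cell_velocity(self) -> np.ndarray:
        """Cell-centred velocity vectors, shape (nx, ny, nz, 3)."""
        uc = 0.5 * (self.u + np.roll(self.u, -1, axis=0))
        vc = 0.5 * (self.v + np.roll(self.v, -1, axis=1))
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        out = np.stack([uc, vc, wc], axis=-1)
        out[~self.fluid_mask] = 0.0
        return out

    def max_divergence(self) -> float:
        """Largest |div V| over fluid cells, in 1/s."""
        h = self.grid.voxel_size * NM
        div = (
            np.roll(self.u, -1, axis=0)
            - self.u
            + np.roll(self.v, -1, axis=1)
            - self.v
            + self.w[:, :, 1:]
            - self.w[:, :, :-1]
        ) / h
        return float(np.max(np.abs(div[self.fluid_mask]))) if np.any(self.fluid_mask) else 0.0


@dataclass(frozen=True)
class FlowSummary:
    volumetric_flow_rate: float  # m^3/s
    mean_velocity: float  # superficial through-thickness velocity, m/s
    mean_pore_velocity: float  # interstitial through-thickness velocity, m/s
    permeability: float  # m^2
    conductivity_per_area: float  # m s^-1 Pa^-1
    reynolds: float
    flux_imbalance: float  # max relative deviation of per-plane flux


def _percolating_fluid(mask: np.ndarray, periodic: bool) -> Tuple[np.ndarray, bool]:
    """Fluid cells connected to either z-face; True when inlet joins outlet."""
    fluid = ~mask
    labels, n = ndi.label(fluid)
    if n == 0:
        return np.zeros_like(fluid), False
    if periodic:
        parent = np.arange(n + 1)

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for axis in (0, 1):
            la = np.take(labels, 0, axis=axis)
            lb = np.take(labels, -1, axis=axis)
            both = (la > 0) & (lb > 0)
            for a, b in set(zip(la[both].ravel(), lb[both].ravel())):
                union(int(a), int(b))
        roots = np.array([find(i) for i in range(n + 1)])
        labels = roots[labels]
    inlet = set(np.unique(labels[:, :, 0])) - {0}
    outlet = set(np.unique(labels[:, :, -1])) - {0}
    keep = inlet | outlet
    keep_mask = np.isin(labels, sorted(keep)) & fluid
    return keep_mask, len(inlet & outlet) > 0


def solve_stokes(
    grid: VoxelGrid,
    fluid: FluidProps = FluidProps(),
    dp: float = 1000.0,
    rtol: float = 1e-8,
    maxiter: Optional[int] = None,
    lateral: str = "periodic",
) -> FlowField:
    """Solve pressure-driven Stokes flow through the grid.

    ``dp`` (Pa) is applied between ghost reservoirs half a voxel outside
    the inlet (k=0) and outlet (k=nz-1) faces.  ``lateral`` selects the
    x/y boundary treatment: "periodic" or "wall" (no-slip side walls).
    A non-percolating geometry returns a zero field flagged
    ``percolating=False`` rather than raising.
    """
    if dp < 0:
        raise ValueError("dp must be >= 0")
    if lateral not in ("periodic", "wall"):
        raise ValueError("lateral must be 'periodic' or 'wall'")
    periodic = lateral == "periodic"
    mask = grid.mask
    nx, ny, nz = mask.shape
    h = grid.voxel_size * NM

    F, percolates = _percolating_fluid(mask, periodic)
    zero = FlowField(
        u=np.zeros((nx, ny, nz)),
        v=np.zeros((nx, ny, nz)),
        w=np.zeros((nx, ny, nz + 1)),
        pressure=np.where(F, 0.0, np.nan),
        dp=dp,
        grid=grid,
        fluid=fluid,
        percolating=percolates,
        residual=0.0,
        fluid_mask=F,
    )
    if not percolates or dp == 0.0:
        return zero

    solid = ~F  # includes pruned pockets: they carry no flow

    # --- unknown numbering -------------------------------------------------
    def shift(arr, ax, d):
        """Neighbour lookup with periodic wrap laterally."""
        return np.roll(arr, d, axis=ax)

    Ufree = F & shift(F, 0, 1)
    Vfree = F & shift(F, 1, 1)
    if not periodic:
        Ufree[0, :, :] = False  # face on the domain edge is a wall
        Vfree[:, 0, :] = False
    Wfree = np.zeros((nx, ny, nz + 1), dtype=bool)
    Wfree[:, :, 0] = F[:, :, 0]
    Wfree[:, :, 1:nz] = F[:, :, :-1] & F[:, :, 1:]
    Wfree[:, :, nz] = F[:, :, nz - 1]

    Uwall = solid & shift(solid, 0, 1)
    Vwall = solid & shift(solid, 1, 1)
    Wwall = np.zeros((nx, ny, nz + 1), dtype=bool)
    Wwall[:, :, 1:nz] = solid[:, :, :-1] & solid[:, :, 1:]
    Wwall[:, :, 0] = solid[:, :, 0]
    Wwall[:, :, nz] = solid[:, :, nz - 1]
    if not periodic:
        # domain side faces are walls for tangential components
        pass  # handled per-neighbour below via the "edge" marker

    nu, nv, nw = int(Ufree.sum()), int(Vfree.sum()), int(Wfree.sum())
    uid = np.full(Ufree.shape, -1, dtype=np.int64)
    vid = np.full(Vfree.shape, -1, dtype=np.int64)
    wid = np.full(Wfree.shape, -1, dtype=np.int64)
    uid[Ufree] = np.arange(nu)
    vid[Vfree] = np.arange(nu, nu + nv)
    wid[Wfree] = np.arange(nu + nv, nu + nv + nw)
    nvel = nu + nv + nw

    cid = np.full(mask.shape, -1, dtype=np.int64)
    npr = int(F.sum())
    cid[F] = np.arange(npr)

    rows, cols, vals = [], [], []
    diag = np.zeros(nvel)
    rhs = np.zeros(nvel + npr)

    def add_laplacian(free, wall, ids):
        my = ids[free]
        dg = np.zeros(my.size)
        for ax in (0, 1, 2):
            for d in (1, -1):
                if ax < 2:
                    nb_free = shift(free, ax, d)[free]
                    nb_wall = shift(wall, ax, d)[free]
                    nb_id = shift(ids, ax, d)[free]
                    if not periodic:
                        # crossing the domain edge means a solid side wall
                        edge = np.zeros_like(free)
                        if d == 1:
                            idx = [slice(None)] * free.ndim
                            idx[ax] = 0
                            edge[tuple(idx)] = True
                        else:
                            idx = [slice(None)] * free.ndim
                            idx[ax] = free.shape[ax] - 1
                            edge[tuple(idx)] = True
                        edge = edge[free]
                        nb_free = nb_free & ~edge
                        nb_wall = nb_wall | edge
                else:
                    # z never wraps: out-of-range neighbours are zero-gradient
                    n3 = free.shape[2]
                    nb_free = np.zeros_like(free)
                    nb_wall = np.zeros_like(free)
                    nb_id = np.full_like(ids, -1)
                    if d == 1:
                        nb_free[:, :, 1:] = free[:, :, :-1]
                        nb_wall[:, :, 1:] = wall[:, :, :-1]
                        nb_id[:, :, 1:] = ids[:, :, :-1]
                        outside = np.zeros_like(free)
                        outside[:, :, 0] = True
                    else:
                        nb_free[:, :, :-1] = free[:, :, 1:]
                        nb_wall[:, :, :-1] = wall[:, :, 1:]
                        nb_id[:, :, :-1] = ids[:, :, 1:]
                        outside = np.zeros_like(free)
                        outside[:, :, n3 - 1] = True
                    outside = outside[free]
                    nb_free = nb_free[free] & ~outside
                    nb_wall = nb_wall[free] & ~outside
                    nb_id = nb_id[free]
                    # out-of-range z neighbours are zero-gradient: no term
                    sel = nb_free
                    rows.append(my[sel])
                    cols.append(nb_id[sel])
                    vals.append(-np.ones(int(sel.sum())))
                    inside = ~outside
                    dg += np.where(inside & nb_wall, 2.0, 0.0)
                    dg += np.where(inside & ~nb_wall, 1.0, 0.0)  # free or zero face
                    continue
                sel = nb_free
                rows.append(my[sel])
                cols.append(nb_id[sel])
                vals.append(-np.ones(int(sel.sum())))
                dg += np.where(nb_wall, 2.0, 1.0)
        diag[my] = dg

    add_laplacian(Ufree, Uwall, uid)
    add_laplacian(Vfree, Vwall, vid)
    add_laplacian(Wfree, Wwall, wid)
    rows.append(np.arange(nvel))
    cols.append(np.arange(nvel))
    vals.append(diag.copy())

    # --- pressure gradient / divergence coupling ---------------------------
    def couple(face_ids, cell_plus, cell_minus):
        """G entries: +1 on the plus cell, -1 on the minus cell."""
        f = face_ids
        for cells, sgn in ((cell_plus, 1.0), (cell_minus, -1.0)):
            ok = cells >= 0
            rows.append(f[ok])
            cols.append(nvel + cells[ok])
            vals.append(np.full(int(ok.sum()), sgn))
            # symmetric transpose block (continuity)
            rows.append(nvel + cells[ok])
            cols.append(f[ok])
            vals.append(np.full(int(ok.sum()), sgn))

    couple(uid[Ufree], cid[Ufree], shift(cid, 0, 1)[Ufree])
    couple(vid[Vfree], cid[Vfree], shift(cid, 1, 1)[Vfree])
    # w internal faces
    Wint = Wfree.copy()
    Wint[:, :, 0] = False
    Wint[:, :, nz] = False
    kplus = np.zeros_like(wid)
    kminus = np.zeros_like(wid)
    kplus[:, :, :nz] = cid
    kminus[:, :, 1:] = cid
    couple(wid[Wint], kplus[Wint], kminus[Wint])
    # inlet faces: minus cell is the ghost reservoir at scaled pressure 1
    inlet_sel = Wfree[:, :, 0]
    f_in = wid[:, :, 0][inlet_sel]
    c_in = cid[:, :, 0][inlet_sel]
    couple(f_in, c_in, np.full(f_in.size, -1))
    rhs[f_in] += 1.0  # ghost p_hat = 1 moved to the right-hand side
    # outlet faces: plus cell is the ghost at scaled pressure 0
    outlet_sel = Wfree[:, :, nz]
    f_out = wid[:, :, nz][outlet_sel]
    c_out = cid[:, :, nz - 1][outlet_sel]
    couple(f_out, np.full(f_out.size, -1), c_out)

    n = nvel + npr
    K = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    # --- solve -------------------------------------------------------------
    dprec = np.ones(n)
    dprec[:nvel] = 1.0 / np.maximum(diag, 1.0)
    M = LinearOperator((n, n), matvec=lambda x: dprec * x)
    if maxiter is None:
        maxiter = 40 * (nx + ny + nz) + 2000
    x, info = minres(K, rhs, rtol=rtol, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(K @ x - rhs) / np.linalg.norm(rhs))

    scale = dp * h / fluid.viscosity  # voxel-unit velocity -> m/s
    u = np.zeros(Ufree.shape)
    v = np.zeros(Vfree.shape)
    w = np.zeros(Wfree.shape)
    u[Ufree] = x[uid[Ufree]] * scale
    v[Vfree] = x[vid[Vfree]] * scale
    w[Wfree] = x[wid[Wfree]] * scale
    pressure = np.full(mask.shape, np.nan)
    pressure[F] = x[nvel + cid[F]] * dp

    return FlowField(
        u=u,
        v=v,
        w=w,
        pressure=pressure,
        dp=dp,
        grid=grid,
        fluid=fluid,
        percolating=True,
        residual=res,
        fluid_mask=F,
    )


def summarize_flow(
    field: FlowField,
    grid: Optional[VoxelGrid] = None,
    fluid: Optional[FluidProps] = None,
    characteristic_diameter: float = 20.0,
) -> FlowSummary:
    """Upscale a flow solution: Darcy permeability, conductivity, Reynolds.

    ``characteristic_diameter`` (nm) is the particle scale entering the
    Reynolds number; the default is the fibril diameter.  The permeability
    uses the one-dimensional Darcy law k = Q mu L / (A dP) with L the
    membrane thickness and A the full tile cross-section.
    """
    grid = grid or field.grid
    fluid = fluid or field.fluid
    h = grid.voxel_size * NM
    nx, ny, nz = grid.shape
    area = nx * ny * h * h
    if field.dp == 0:
        raise ValueError("permeability is undefined at zero pressure drop")
    planes = field.w.sum(axis=(0, 1)) * h * h  # m^3/s through each z-face plane
    Q = float(planes.mean())
    if Q == 0.0:
        return FlowSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    imbalance = float(np.max(np.abs(planes - Q)) / abs(Q))
    mean_v = Q / area
    porosity = float((field.fluid_mask).sum() / field.fluid_mask.size)
    mean_pore_v = mean_v / porosity if porosity > 0 else 0.0
    L = nz * h
    k = Q * fluid.viscosity * L / (area * field.dp)
    cond = Q / (area * field.dp)
    re = fluid.density * abs(mean_pore_v) * characteristic_diameter * NM / fluid.viscosity
    return FlowSummary(
        volumetric_flow_rate=Q,
        mean_velocity=mean_v,
        mean_pore_velocity=mean_pore_v,
        permeability=k,
        conductivity_per_area=cond,
        reynolds=re,
        flux_imbalance=imbalance,
    )


def per_pore_flux(field: FlowField, pg) -> dict:
    """Fraction of the total flux carried by each pore.

    A pore's flux is the z-projected flow through its voxels averaged over
    the z-slices it occupies, normalised by the total flow rate.  Over any
    full cross-section the fractions sum to one up to discretisation.
    """
    labels = pg.labels
    if labels is None or labels.shape != field.grid.shape:
        raise ValueError("pore graph does not match the flow geometry")
    h = field.grid.voxel_size * NM
    wc = 0.5 * (field.w[:, :, :-1] + field.w[:, :, 1:])  # cell-centred w
    nxl, nyl, nzl = labels.shape
    nlab = int(labels.max())
    if nlab == 0:
        return {}
    planes = field.w.sum(axis=(0, 1)) * h * h
    Q = float(planes.mean())
    flat = (labels.ravel()) * nzl + np.tile(np.arange(nzl), nxl * nyl).reshape(
        nxl, nyl, nzl
    ).ravel()
    sums = np.bincount(flat, weights=(wc * h * h).ravel(), minlength=(nlab + 1) * nzl)
    sums = sums.reshape(nlab + 1, nzl)
    occupied = np.bincount(flat, minlength=(nlab + 1) * nzl).reshape(nlab + 1, nzl) > 0
    out = {}
    for pid in range(1, nlab + 1):
        ks = np.flatnonzero(occupied[pid])
        if ks.size == 0 or Q == 0.0:
            out[pid] = 0.0
            continue
        out[pid] = float(sums[pid, ks].mean() / Q)
    return out
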