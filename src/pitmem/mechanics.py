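"""Membrane mechanics: Cox shear-lag estimate and beam-network tension.

Two complementary estimators of pit-membrane stiffness:

* :func:`cox_modulus` — the classical shear-lag result for a planar random
  fibre network, ``E = vf * Ef / 3``: effective in-plane modulus from the
  fibril volume fraction and the single-fibril modulus alone.

* :func:`uniaxial_tension` — a direct displacement-controlled tensile test
  on the deposited fibril network.  Each fibril becomes a chain of 3D
  Euler–Bernoulli beam elements split at fibril–fibril contacts; contacts
  are rigid welds (both fibrils share the contact node, so forces and
  moments transfer).  Elements whose axial strain exceeds the failure
  strain are deleted between load steps, which produces the progressive
  fracture of the mat; with no failure criterion the response is exactly
  linear.

Geometry is nm on input and converted to SI inside the solver; forces are
N, stresses Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .deposition import FibrilNetwork
from .geometry import segment_to_segments_3d

__all__ = [
    "FibrilMaterial",
    "BeamModel",
    "MechanicalResponse",
    "cox_modulus",
    "build_beam_model",
    "uniaxial_tension",
    "uniform_stretch",
]

NM = 1e-9


def cox_modulus(vf: float, Ef: float) -> float:
    """Cox shear-lag effective modulus of a random in-plane fibre network.

    Parameters
    ----------
    vf : fibril volume fraction, in [0, 1].
    Ef : Young's modulus of a single microfibril (Pa).

    Returns ``vf * Ef / 3`` (Pa), exactly.
    """
    if not 0.0 <= vf <= 1.0:
        raise ValueError("vf must lie in [0, 1]")
    if Ef <= 0:
        raise ValueError("Ef must be positive")
    return vf * Ef / 3.0


@dataclass(frozen=True)
class FibrilMaterial:
    """Linear-elastic fibril: modulus, Poisson ratio, optional failure strain."""

    Ef: float  # Pa
    failure_strain: Optional[float] = None
    poisson: float = 0.3

    def __post_init__(self):
        if self.Ef <= 0:
            raise ValueError("Ef must be positive")
        if self.failure_strain is not None and self.failure_strain <= 0:
            raise ValueError("failure_strain must be positive when set")


@dataclass
class BeamModel:
    """Beam discretisation of a fibril network.

    nodes: (N, 3) nm; elements: (node_a, node_b, diameter_nm, fibril_index);
    grips: node index sets at the two opposite edges along ``grip_axis``.
    """

    nodes: np.ndarray
    elements: List[Tuple[int, int, float, int]]
    grip_min: np.ndarray
    grip_max: np.ndarray
    grip_axis: int
    domain: Tuple[float, float]
    thickness: float
    connected: bool
    n_contacts: int

    def element_graph(self, active: Optional[Sequence[bool]] = None):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        for e, (a, b, _, _) in enumerate(self.elements):
            if active is None or active[e]:
                g.add_edge(a, b)
        return g


def find_contacts(network: FibrilNetwork, tol_rel: float = 1e-6):
    """All fibril pairs whose axes approach within the sum of radii.

    Returns a list of (i, j, s_i, s_j, contact_point) with the contact point
    midway between the two closest axis points.
    """
    p0, p1 = network.endpoints
    radii = network.radii
    contacts = []
    for i in range(1, len(network)):
        dist, s, t, pa, pb = segment_to_segments_3d(p0[i], p1[i], p0[:i], p1[:i])
        rsum = radii[i] + radii[:i]
        hit = dist <= rsum * (1.0 + tol_rel) + 1e-9
        for j in np.flatnonzero(hit):
            contacts.append((i, int(j), float(s[j]), float(t[j]), 0.5 * (pa[j] + pb[j])))
    return contacts


def build_beam_model(
    network: FibrilNetwork, grip_axis: str = "y", tol_rel: float = 1e-6
) -> BeamModel:
    """Mesh a fibril network into welded beam elements with grip node sets.

    Grip sets collect nodes within one fibril diameter of the two opposite
    domain edges along ``grip_axis``.  ``connected`` records whether the
    welded network actually spans between the grips.
    """
    if len(network) == 0:
        raise ValueError("cannot build a beam model from an empty network")
    axis = {"x": 0, "y": 1}[grip_axis]
    p0, p1 = network.endpoints
    contacts = find_contacts(network, tol_rel)

    nodes: List[np.ndarray] = []
    elements: List[Tuple[int, int, float, int]] = []
    # per-fibril breakpoints: (arc parameter, node id)
    breaks: List[List[Tuple[float, int]]] = [[] for _ in range(len(network))]

    def add_node(p) -> int:
        nodes.append(np.asarray(p, dtype=float))
        return len(nodes) - 1

    for i in range(len(network)):
        breaks[i].append((0.0, add_node(p0[i])))
        breaks[i].append((1.0, add_node(p1[i])))
    for i, j, s, t, point in contacts:
        nid = add_node(point)
        breaks[i].append((s, nid))
        breaks[j].append((t, nid))

    node_arr = np.array(nodes)
    min_len = 1e-6  # nm; coincident breakpoints merge into one node
    parent = list(range(len(nodes)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, br in enumerate(breaks):
        br.sort(key=lambda x: x[0])
        length = np.linalg.norm(p1[i] - p0[i])
        prev_s, prev_id = br[0]
        for s, nid in br[1:]:
            if (s - prev_s) * length < min_len:
                ra, rb = find(prev_id), find(nid)
                if ra != rb:
                    parent[rb] = ra
                continue
            elements.append((prev_id, nid, float(2 * network.radii[i]), i))
            prev_s, prev_id = s, nid
    elements = [
        (find(a), find(b), d, i) for a, b, d, i in elements if find(a) != find(b)
    ]

    extent = network.domain[axis]
    d_max = float(np.max(network.radii) * 2)
    coord = node_arr[:, axis]
    grip_min = np.flatnonzero(coord <= d_max)
    grip_max = np.flatnonzero(coord >= extent - d_max)

    model = BeamModel(
        nodes=node_arr,
        elements=elements,
        grip_min=grip_min,
        grip_max=grip_max,
        grip_axis=axis,
        domain=network.domain,
        thickness=network.thickness,
        connected=False,
        n_contacts=len(contacts),
    )
    g = model.element_graph()
    comp = {n: c for c, nodes_ in enumerate(_components(g)) for n in nodes_}
    model.connected = bool(
        {comp[n] for n in grip_min if n in comp} & {comp[n] for n in grip_max if n in comp}
    )
    return model


def _components(g):
    import networkx as nx

    return list(nx.connected_components(g))


@dataclass
class MechanicalResponse:
    strain: np.ndarray
    force: np.ndarray  # N
    stress: np.ndarray  # nominal, Pa
    n_broken: np.ndarray
    broken_sets: List[Set[int]]
    displacement: Optional[np.ndarray]  # (N, 3) m, last solved step
    failed: bool
    effective_modulus: float  # Pa, initial slope


def _element_stiffness(E: float, G: float, L: float, d: float, direction: np.ndarray):
    """12x12 global-frame Euler-Bernoulli stiffness for a circular section."""
    r = d / 2.0
    A = np.pi * r**2
    Iy = Iz = np.pi * r**4 / 4.0
    J = np.pi * r**4 / 2.0
    k = np.zeros((12, 12))
    EA = E * A / L
    GJ = G * J / L
    a = 12 * E * Iz / L**3
    b = 6 * E * Iz / L**2
    c = 4 * E * Iz / L
    d2 = 2 * E * Iz / L
    # axial
    k[0, 0] = k[6, 6] = EA
    k[0, 6] = k[6, 0] = -EA
    # torsion
    k[3, 3] = k[9, 9] = GJ
    k[3, 9] = k[9, 3] = -GJ
    # bending about z (displacement y, rotation z): dofs 1,5,7,11
    for (i, j, v) in [
        (1, 1, a), (1, 5, b), (1, 7, -a), (1, 11, b),
        (5, 5, c), (5, 7, -b), (5, 11, d2),
        (7, 7, a), (7, 11, -b),
        (11, 11, c),
    ]:
        k[i, j] = v
        k[j, i] = v
    # bending about y (displacement z, rotation y): dofs 2,4,8,10
    for (i, j, v) in [
        (2, 2, a), (2, 4, -b), (2, 8, -a), (2, 10, -b),
        (4, 4, c), (4, 8, b), (4, 10, d2),
        (8, 8, a), (8, 10, b),
        (10, 10, c),
    ]:
        k[i, j] = v
        k[j, i] = v
    # rotation local->global
    ex = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(ex @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    R = np.vstack([ex, ey, ez])
    T = np.kron(np.eye(4), R)
    return T.T @ k @ T


def _assemble(model: BeamModel, material: FibrilMaterial, active: np.ndarray):
    nodes_m = model.nodes * NM
    ndof = 6 * len(model.nodes)
    G = material.Ef / (2.0 * (1.0 + material.poisson))
    ii, jj, vv = [], [], []
    for e, (a, b, d_nm, _) in enumerate(model.elements):
        if not active[e]:
            continue
        vec = nodes_m[b] - nodes_m[a]
        L = np.linalg.norm(vec)
        if L < 1e-15:
            continue
        ke = _element_stiffness(material.Ef, G, L, d_nm * NM, vec)
        dofs = np.concatenate([6 * a + np.arange(6), 6 * b + np.arange(6)])
        ii.append(np.repeat(dofs, 12))
        jj.append(np.tile(dofs, 12))
        vv.append(ke.ravel())
    K = sparse.csr_matrix(
        (np.concatenate(vv), (np.concatenate(ii), np.concatenate(jj))),
        shape=(ndof, ndof),
    )
    return K


def uniaxial_tension(
    model: BeamModel,
    material: FibrilMaterial,
    max_strain: float = 0.02,
    steps: int = 10,
) -> MechanicalResponse:
    """Displacement-controlled uniaxial tension of the welded fibril network.

    One grip is clamped, the other is displaced along the grip axis in
    equal strain increments up to ``max_strain``.  A linear-elastic beam
    solve is done per step; elements whose axial strain exceeds the
    material's failure strain are removed before the next step.  When
    fracture disconnects the grips the response is truncated and flagged
    ``failed`` instead of raising.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not model.connected:
        raise ValueError("disconnected specimen: no load path between the grips")
    axis = model.grip_axis
    L0 = model.domain[axis] * NM
    width = model.domain[1 - axis] * NM
    area = width * max(model.thickness, 1e-9) * NM

    n_nodes = len(model.nodes)
    ndof = 6 * n_nodes
    active = np.ones(len(model.elements), dtype=bool)
    broken: Set[int] = set()
    broken_sets: List[Set[int]] = []
    strains = np.linspace(max_strain / steps, max_strain, steps)
    forces = np.zeros(steps)
    n_broken = np.zeros(steps, dtype=int)
    disp = None
    failed = False

    # grips are clamps: all six dofs prescribed (also removes free torsion
    # spin of an uncontacted spanning fibril)
    fixed_dofs = (6 * model.grip_min[:, None] + np.arange(6)[None, :]).ravel()
    moving_dofs = (6 * model.grip_max[:, None] + np.arange(6)[None, :]).ravel()
    pull_dofs = 6 * model.grip_max + axis

    nodes_m = model.nodes * NM
    for step, eps in enumerate(strains):
        # drop pieces no longer tied to both grips (rigid-body modes)
        g = model.element_graph(active)
        comp_of = {}
        for c, comp in enumerate(_components(g)):
            for nd in comp:
                comp_of[nd] = c
        span = {comp_of[n] for n in model.grip_min} & {comp_of[n] for n in model.grip_max}
        if not span:
            failed = True
            strains = strains[:step]
            forces = forces[:step]
            n_broken = n_broken[:step]
            break
        live_nodes = np.array([n for n in range(n_nodes) if comp_of.get(n) in span])
        live_elem = active.copy()
        for e, (a, b, _, _) in enumerate(model.elements):
            if live_elem[e] and comp_of.get(a) not in span:
                live_elem[e] = False

        K = _assemble(model, material, live_elem)
        delta = eps * L0
        u = np.zeros(ndof)
        u[pull_dofs] = delta

        live_dofs = np.concatenate([6 * live_nodes[:, None] + np.arange(6)[None, :]]).ravel()
        prescribed = np.concatenate([fixed_dofs, moving_dofs])
        pres_set = set(prescribed.tolist())
        free = np.array([d for d in live_dofs if d not in pres_set], dtype=int)

        Kff = K[free][:, free]
        rhs = -K[free][:, prescribed] @ u[prescribed]
        uf = spsolve(Kff.tocsc(), rhs)
        if not np.all(np.isfinite(uf)):
            failed = True
            strains = strains[:step]
            forces = forces[:step]
            n_broken = n_broken[:step]
            break
        u[free] = uf
        reactions = K @ u
        forces[step] = float(reactions[pull_dofs].sum())
        disp = u.reshape(-1, 6)[:, :3].copy()

        # element axial strains -> fracture
        if material.failure_strain is not None:
            for e, (a, b, _, _) in enumerate(model.elements):
                if not live_elem[e] or e in broken:
                    continue
                vec = nodes_m[b] - nodes_m[a]
                Le = np.linalg.norm(vec)
                if Le < 1e-15:
                    continue
                ex = vec / Le
                eps_e = float((disp[b] - disp[a]) @ ex / Le)
                if eps_e > material.failure_strain:
                    broken.add(e)
                    active[e] = False
        n_broken[step] = len(broken)
        broken_sets.append(set(broken))

    stress = forces / area
    eff = float(stress[0] / strains[0]) if len(strains) else 0.0
    return MechanicalResponse(
        strain=strains,
        force=forces,
        stress=stress,
        n_broken=n_broken,
        broken_sets=broken_sets,
        displacement=disp,
        failed=failed,
        effective_modulus=max(eff, 0.0),
    )


def uniform_stretch(
    model: BeamModel,
    material: FibrilMaterial,
    max_strain: float = 0.02,
    steps: int = 5,
) -> MechanicalResponse:
    """Equi-biaxial (uniform) stretching: both in-plane axes pulled equally.

    Thin variant of :func:`uniaxial_tension` approximating tension in all
    directions; grip sets on all four edges move outward along their axes.
    """
    # build the orthogonal grip sets on the fly
    axis = model.grip_axis
    other = 1 - axis
    coord = model.nodes[:, other]
    d_max = max(d for _, _, d, _ in model.elements)
    omin = np.flatnonzero(coord <= d_max)
    omax = np.flatnonzero(coord >= model.domain[other] - d_max)
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not model.connected:
        raise ValueError("disconnected specimen: no load path between the grips")

    L_a = model.domain[axis] * NM
    L_o = model.domain[other] * NM
    area = (model.domain[other] * NM) * max(model.thickness, 1e-9) * NM
    ndof = 6 * len(model.nodes)
    active = np.ones(len(model.elements), dtype=bool)
    strains = np.linspace(max_strain / steps, max_strain, steps)
    forces = np.zeros(steps)
    disp = None

    edge_nodes = np.unique(
        np.concatenate([model.grip_min, model.grip_max, omin, omax])
    )
    rot_dofs = (6 * edge_nodes[:, None] + np.arange(3, 6)[None, :]).ravel()
    prescribed = np.unique(
        np.concatenate(
            [
                6 * model.grip_min + axis,
                6 * model.grip_max + axis,
                6 * omin + other,
                6 * omax + other,
                rot_dofs,
            ]
        )
    )
    # pin rigid-body motion: clamp remaining translations of one corner-most node
    anchor = int(model.grip_min[0])
    pin = 6 * anchor + np.arange(3)
    prescribed = np.unique(np.concatenate([prescribed, pin]))

    # restrict to the component spanning the grips: floating fragments and
    # single-edge dangles have unconstrained rigid modes
    g = model.element_graph(active)
    comp_of = {}
    for c, comp in enumerate(_components(g)):
        for nd in comp:
            comp_of[nd] = c
    span = {comp_of[n] for n in model.grip_min} & {comp_of[n] for n in model.grip_max}
    live_nodes = np.array([n for n in range(len(model.nodes)) if comp_of.get(n) in span])
    live = active.copy()
    for e, (a, b, _, _) in enumerate(model.elements):
        if live[e] and comp_of.get(a) not in span:
            live[e] = False
    K = _assemble(model, material, live)
    live_dofs = (6 * live_nodes[:, None] + np.arange(6)[None, :]).ravel()
    pres_set = set(prescribed.tolist())
    free = np.array([d for d in live_dofs if d not in pres_set], dtype=int)
    for step, eps in enumerate(strains):
        u = np.zeros(ndof)
        u[6 * model.grip_max + axis] = eps * L_a
        u[6 * omax + other] = eps * L_o
        rhs = -K[free][:, prescribed] @ u[prescribed]
        uf = spsolve(K[free][:, free].tocsc(), rhs)
        u[free] = uf
        reactions = K @ u
        forces[step] = float(reactions[6 * model.grip_max + axis].sum())
        disp = u.reshape(-1, 6)[:, :3].copy()
    stress = forces / area
    eff = float(stress[0] / strains[0]) if len(strains) else 0.0
    return MechanicalResponse(
        strain=strains,
        force=forces,
        stress=stress,
        n_broken=np.zeros(len(strains), dtype=int),
        broken_sets=[set() for _ in strains],
        displacement=disp,
        failed=False,
        effective_modulus=max(eff, 0.0),
    )
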