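"""Random sequential deposition of rigid cellulose microfibrils.

The generator emulates how a pit membrane's microfibril mat is laid down:
straight, rigid, horizontal fibrils fall one by one onto a flat plate and
stop at the first contact with the plate or with a previously deposited
fibril.  Orientation and in-plane position of every fibril are uniformly
random.  Because both the candidate and all deposited fibrils are
horizontal, the first-contact height has a closed form: for every deposited
fibril whose in-plane axis distance ``d_xy`` is below the sum of radii
``R``, the candidate locks at axis height ``z_j + sqrt(R^2 - d_xy^2)``; the
resting height is the maximum of those contact heights and the plate height
(one radius).

Density control
---------------
Pure single-candidate ballistic deposition of long thin rods produces very
open mats.  The number of trial poses per deposited fibril
(``candidates_per_step``) adjusts the deposition sequence: each step draws
that many independent poses and keeps the lowest-resting one, which packs
the mat tighter without ever bending or moving a settled fibril.  One
candidate per step recovers plain ballistic deposition.

All lengths are nm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .geometry import (
    clip_segment_circle,
    clip_segment_rect,
    segment_to_segments_2d,
)

__all__ = [
    "DepositionParams",
    "Microfibril",
    "FibrilNetwork",
    "resting_height",
    "deposit_network",
    "clip_circular",
    "volume_fraction",
    "analytic_solid_volume",
    "write_network_csv",
    "read_network_csv",
]

#: length specification: a constant or ("uniform", low, high)
LengthSpec = Union[float, Tuple[str, float, float]]


def _sample_length(rng: np.random.Generator, spec: LengthSpec) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    raise ValueError(f"unknown length distribution {spec!r}")


def _spec_min(spec: LengthSpec) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    return float(min(spec[1], spec[2]))


@dataclass(frozen=True)
class DepositionParams:
    """Parameters of a deposition run.

    Defaults emulate an angiosperm pit membrane: a 500 x 500 nm tile of
    20 nm cellulose microfibrils deposited until the mat is roughly 300 nm
    thick.  Exactly one of ``target_count`` / ``target_volume_fraction``
    must be set.
    """

    domain_x: float = 500.0
    domain_y: float = 500.0
    fibril_diameter: LengthSpec = 20.0
    fibril_length: LengthSpec = 1000.0
    target_count: Optional[int] = 200
    target_volume_fraction: Optional[float] = None
    in_plane_only: bool = True
    seed: int = 0
    clip_radius: Optional[float] = None
    candidates_per_step: int = 100
    step_batch: int = 1
    max_fibrils: int = 50_000
    contact_rtol: float = 1e-6

    def __post_init__(self):
        if self.domain_x <= 0 or self.domain_y <= 0:
            raise ValueError("domain extents must be positive")
        if _spec_min(self.fibril_diameter) <= 0:
            raise ValueError("fibril diameter must be positive")
        if _spec_min(self.fibril_length) <= 0:
            raise ValueError("fibril length must be positive")
        has_count = self.target_count is not None
        has_vf = self.target_volume_fraction is not None
        if has_count == has_vf:
            raise ValueError(
                "exactly one of target_count / target_volume_fraction must be set"
            )
        if has_count and self.target_count < 0:
            raise ValueError("target_count must be >= 0")
        if has_vf and not (0.0 <= self.target_volume_fraction < 1.0):
            raise ValueError("target_volume_fraction must lie in [0, 1)")
        if not self.in_plane_only:
            raise ValueError("only in-plane (horizontal) deposition is implemented")
        if self.candidates_per_step < 1:
            raise ValueError("candidates_per_step must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("fibril_diameter", "fibril_length"):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DepositionParams":
        d = dict(d)
        for key in ("fibril_diameter", "fibril_length"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class Microfibril:
    """A straight cylindrical fibril segment with a horizontal axis."""

    p0: np.ndarray
    p1: np.ndarray
    diameter: float
    deposit_index: int

    def __post_init__(self):
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=float))
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float))
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if np.allclose(self.p0, self.p1):
            raise ValueError("degenerate fibril: p0 == p1")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def z(self) -> float:
        return float(self.p0[2])

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))


class FibrilNetwork:
    """An ordered collection of deposited fibrils on a rectangular tile."""

    def __init__(
        self,
        fibrils: Sequence[Microfibril],
        domain: Tuple[float, float],
        params: Optional[DepositionParams] = None,
        seed: Optional[int] = None,
    ):
        self.fibrils = list(fibrils)
        self.domain = (float(domain[0]), float(domain[1]))
        self.params = params
        self.seed = seed
        self._rebuild_arrays()

    def _rebuild_arrays(self) -> None:
        n = len(self.fibrils)
        self._p0 = np.empty((n, 3))
        self._p1 = np.empty((n, 3))
        self._radius = np.empty(n)
        for i, f in enumerate(self.fibrils):
            self._p0[i] = f.p0
            self._p1[i] = f.p1
            self._radius[i] = f.radius

    def __len__(self) -> int:
        return len(self.fibrils)

    @property
    def endpoints(self) -> Tuple[np.ndarray, np.ndarray]:
        return self._p0, self._p1

    @property
    def radii(self) -> np.ndarray:
        return self._radius

    @property
    def thickness(self) -> float:
        """Membrane thickness: highest fibril crown (axis height + radius)."""
        if not self.fibrils:
            return 0.0
        return float(np.max(self._p0[:, 2] + self._radius))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "deposit_index": f.deposit_index,
                "x0": f.p0[0],
                "y0": f.p0[1],
                "z0": f.p0[2],
                "x1": f.p1[0],
                "y1": f.p1[1],
                "z1": f.p1[2],
                "diameter_nm": f.diameter,
            }
            for f in self.fibrils
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "deposit_index",
                "x0",
                "y0",
                "z0",
                "x1",
                "y1",
                "z1",
                "diameter_nm",
            ],
        )


def resting_height(
    a0,
    a1,
    diameter: float,
    network: FibrilNetwork,
) -> float:
    """Axis height at which a horizontal fibril dropped straight down stops.

    ``a0``/``a1`` are the 2D (x, y) endpoints of the candidate axis. Returns
    the lowest z >= diameter/2 at which the candidate first touches the
    plate or a deposited fibril.
    """
    r_c = 0.5 * float(diameter)
    if len(network) == 0:
        return r_c
    p0, p1 = network.endpoints
    d_xy = segment_to_segments_2d(a0, a1, p0[:, :2], p1[:, :2])
    r_sum = network.radii + r_c
    hit = d_xy < r_sum
    if not np.any(hit):
        return r_c
    dz = np.sqrt(np.maximum(r_sum[hit] ** 2 - d_xy[hit] ** 2, 0.0))
    return float(max(r_c, np.max(p0[hit, 2] + dz)))


def _draw_candidate(rng: np.random.Generator, params: DepositionParams):
    """One random horizontal pose: uniform centre in the tile, uniform angle."""
    length = _sample_length(rng, params.fibril_length)
    diameter = _sample_length(rng, params.fibril_diameter)
    cx = rng.uniform(0.0, params.domain_x)
    cy = rng.uniform(0.0, params.domain_y)
    theta = rng.uniform(0.0, np.pi)
    u = np.array([np.cos(theta), np.sin(theta)])
    p0 = np.array([cx, cy]) - 0.5 * length * u
    p1 = np.array([cx, cy]) + 0.5 * length * u
    clipped = clip_segment_rect(p0, p1, 0.0, params.domain_x, 0.0, params.domain_y)
    # the centre lies inside the tile, so the clip never comes back empty
    a0, a1 = clipped
    return a0, a1, diameter


def analytic_solid_volume(network: FibrilNetwork) -> float:
    """Sum of cylinder volumes (nm^3).

    Deposited fibrils touch but never interpenetrate, so pairwise overlap
    has zero volume and the plain sum is the overlap-corrected solid volume.
    """
    p0, p1 = network.endpoints
    if len(network) == 0:
        return 0.0
    lengths = np.linalg.norm(p1 - p0, axis=1)
    return float(np.sum(np.pi * network.radii**2 * lengths))


def deposit_network(params: DepositionParams) -> FibrilNetwork:
    """Run the deposition until the target count or volume fraction is met.

    Deterministic for a fixed seed: two runs with identical parameters
    produce identical fibril tables, and a run with a larger
    ``target_count`` extends a smaller one (same seed prefix).
    """
    rng = np.random.default_rng(params.seed)
    network = FibrilNetwork([], (params.domain_x, params.domain_y), params, params.seed)
    fibrils = network.fibrils
    area = params.domain_x * params.domain_y
    solid_volume = 0.0

    def done() -> bool:
        if params.target_count is not None:
            return len(fibrils) >= params.target_count
        thickness = network.thickness
        if thickness <= 0:
            return False
        return solid_volume / (area * thickness) >= params.target_volume_fraction

    while not done():
        if len(fibrils) >= params.max_fibrils:
            raise RuntimeError(
                f"deposition cap of {params.max_fibrils} fibrils reached before the "
                "target volume fraction; the target exceeds what this deposition "
                "process can pack"
            )
        best = None
        for _ in range(params.candidates_per_step):
            a0, a1, diameter = _draw_candidate(rng, params)
            z = resting_height(a0, a1, diameter, network)
            if best is None or z < best[0]:
                best = (z, a0, a1, diameter)
        z, a0, a1, diameter = best
        fib = Microfibril(
            p0=np.array([a0[0], a0[1], z]),
            p1=np.array([a1[0], a1[1], z]),
            diameter=diameter,
            deposit_index=len(fibrils),
        )
        fibrils.append(fib)
        network._rebuild_arrays()
        solid_volume += np.pi * fib.radius**2 * fib.length

    if params.clip_radius is not None:
        center = (0.5 * params.domain_x, 0.5 * params.domain_y)
        network = clip_circular(network, params.clip_radius, center)
    return network


def clip_circular(
    network: FibrilNetwork, radius: float, center=None
) -> FibrilNetwork:
    """Cut a circular membrane out of the rectangular deposition tile.

    Fibrils wholly outside the vertical cylinder are dropped; crossing
    fibrils are truncated with their new endpoints on the circle. Heights
    are untouched.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if center is None:
        center = (0.5 * network.domain[0], 0.5 * network.domain[1])
    clipped = []
    for f in network.fibrils:
        res = clip_segment_circle(f.p0[:2], f.p1[:2], center, radius)
        if res is None:
            continue
        q0, q1 = res
        if np.allclose(q0, q1):
            continue
        clipped.append(
            Microfibril(
                p0=np.array([q0[0], q0[1], f.z]),
                p1=np.array([q1[0], q1[1], f.z]),
                diameter=f.diameter,
                deposit_index=f.deposit_index,
            )
        )
    return FibrilNetwork(clipped, network.domain, network.params, network.seed)


def volume_fraction(network: FibrilNetwork, region, resolution: Optional[float] = None) -> float:
    """Solid volume fraction of the network within a region.

    ``region`` is either a box ``(x0, x1, y0, y1, z0, z1)`` or a cylinder
    ``("cylinder", cx, cy, radius, z0, z1)``.  Computed by midpoint
    quadrature on a fine grid of the *union* of all fibrils, so tangent
    fibrils are never double-counted.  ``resolution`` defaults to one sixth
    of the smallest fibril diameter.
    """
    if len(network) == 0:
        _region_bounds(region)  # still validate
        return 0.0
    if resolution is None:
        resolution = float(np.min(network.radii)) / 3.0
    (x0, x1, y0, y1, z0, z1), inside = _region_bounds(region)
    if not (x1 > x0 and y1 > y0 and z1 > z0):
        raise ValueError("region must have positive volume")

    def centers(lo, hi):
        n = max(1, int(np.ceil((hi - lo) / resolution)))
        return lo + (np.arange(n) + 0.5) * (hi - lo) / n

    xs, ys, zs = centers(x0, x1), centers(y0, y1), centers(z0, z1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = inside(pts)
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise ValueError("region must have positive volume")
    solid = np.zeros(pts.shape[0], dtype=bool)
    p0, p1 = network.endpoints
    for i in range(len(network)):
        todo = ~solid
        if not np.any(todo):
            break
        inside = _points_in_cylinder(pts[todo], p0[i], p1[i], network.radii[i])
        solid[np.flatnonzero(todo)[inside]] = True
    return float(np.count_nonzero(solid) / keep.sum())


def _points_in_cylinder(pts: np.ndarray, a0: np.ndarray, a1: np.ndarray, r: float) -> np.ndarray:
    """Finite cylinder membership (flat caps, no end hemispheres)."""
    d = a1 - a0
    den = float(d @ d)
    if den < 1e-12:
        return np.zeros(pts.shape[0], dtype=bool)
    t = (pts - a0) @ d / den
    perp = np.linalg.norm(pts - (a0 + t[:, None] * d), axis=1)
    return (t >= 0.0) & (t <= 1.0) & (perp <= r)


def _points_to_segment_3d(pts: np.ndarray, a0: np.ndarray, a1: np.ndarray) -> np.ndarray:
    d = a1 - a0
    den = float(d @ d)
    if den < 1e-12:
        return np.linalg.norm(pts - a0, axis=1)
    t = np.clip((pts - a0) @ d / den, 0.0, 1.0)
    return np.linalg.norm(a0 + t[:, None] * d - pts, axis=1)


def _region_bounds(region):
    if isinstance(region, (tuple, list)) and len(region) == 6 and not isinstance(region[0], str):
        x0, x1, y0, y1, z0, z1 = map(float, region)

        def inside(pts):
            return np.ones(pts.shape[0], dtype=bool)

        return (x0, x1, y0, y1, z0, z1), inside
    if isinstance(region, (tuple, list)) and len(region) == 6 and region[0] == "cylinder":
        _, cx, cy, radius, z0, z1 = region
        cx, cy, radius, z0, z1 = map(float, (cx, cy, radius, z0, z1))
        if radius <= 0:
            raise ValueError("region must have positive volume")

        def inside(pts):
            return (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= radius**2

        return (cx - radius, cx + radius, cy - radius, cy + radius, z0, z1), inside
    raise ValueError(f"unrecognised region spec: {region!r}")


# ---------------------------------------------------------------------------
# fibril table I/O
# ---------------------------------------------------------------------------

def write_network_csv(network: FibrilNetwork, path) -> None:
    """Write the fibril table as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    network.to_frame().to_csv(path, index=False, float_format="%.17g")
    meta = {
        "format": "pitmem-fibril-table",
        "version": 1,
        "seed": network.seed,
        "domain": list(network.domain),
        "params": network.params.to_dict() if network.params else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_network_csv(path) -> FibrilNetwork:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df = df.astype(
        {c: float for c in ("x0", "y0", "z0", "x1", "y1", "z1", "diameter_nm")}
        | {"deposit_index": int}
    )
    meta_path = path.with_suffix(path.suffix + ".json")
    params = None
    seed = None
    domain = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        seed = meta.get("seed")
        domain = meta.get("domain")
        if meta.get("params"):
            params = DepositionParams.from_dict(meta["params"])
    fibrils = [
        Microfibril(
            p0=np.array([row.x0, row.y0, row.z0]),
            p1=np.array([row.x1, row.y1, row.z1]),
            diameter=row.diameter_nm,
            deposit_index=int(row.deposit_index),
        )
        for row in df.itertuples()
    ]
    if domain is None:
        all_xy = np.concatenate([df[["x0", "y0"]].values, df[["x1", "y1"]].values])
        domain = all_xy.max(axis=0) if len(all_xy) else (1.0, 1.0)
    return FibrilNetwork(fibrils, domain, params=params, seed=seed)
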