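"""Pore-graph extraction: analytic fixtures, path counting, obstruction."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from pitmem import DepositionParams, VoxelGrid, deposit_network, extract_pore_graph, fixture_geometry, voxelize


def _two_cavity_grid(h=1.0, R=10.0, neck_r=5.0, W=60.0):
    """Two spherical cavities joined by a narrow vertical cylindrical neck."""
    n = int(W / h)
    c = W / 2
    z1, z2 = W / 4, 3 * W / 4
    xs = (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    mask = np.ones((n, n, n), dtype=bool)
    mask[(X - c) ** 2 + (Y - c) ** 2 + (Z - z1) ** 2 <= R**2] = False
    mask[(X - c) ** 2 + (Y - c) ** 2 + (Z - z2) ** 2 <= R**2] = False
    neck = ((X - c) ** 2 + (Y - c) ** 2 <= neck_r**2) & (Z > z1) & (Z < z2)
    mask[neck] = False
    return VoxelGrid(mask, h)


def _capsule_with_neck(h=1.0, D=20.0, neck=10.0, W=60.0, L=90.0):
    """Spherical cavity of diameter D linked to both faces by necks of the
    given diameter; wide vestibules at the faces make the necks genuine
    saddles, so the cavity's widest through-path bottleneck is the neck."""
    n = int(W / h)
    nz = int(L / h)
    c = W / 2
    xs = (np.arange(n) + 0.5) * h
    zs = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    mask = np.ones((n, n, nz), dtype=bool)
    core = (X - c) ** 2 + (Y - c) ** 2
    mask[core + (Z - L / 2) ** 2 <= (D / 2) ** 2] = False
    mask[(core <= (neck / 2) ** 2)] = False  # neck runs the full height
    # wide vestibules touching inlet and outlet
    mask[(core <= (D / 2) ** 2) & (Z <= L / 5)] = False
    mask[(core <= (D / 2) ** 2) & (Z >= 4 * L / 5)] = False
    return VoxelGrid(mask, h)


class TestExtraction:
    def test_single_through_hole(self):
        grid = fixture_geometry("tube", 2.5, radius=30.0, width=100.0, length=100.0)
        pg = extract_pore_graph(grid)
        assert len(pg) == 1
        (pore,) = pg.pores.values()
        assert pore.touches_inlet and pore.touches_outlet
        assert pore.diameter == pytest.approx(60.0, abs=2 * grid.voxel_size)
        assert pg.percolates()

    def test_two_cavities_one_constriction(self):
        grid = _two_cavity_grid()
        pg = extract_pore_graph(grid)
        assert len(pg) == 2
        assert len(pg.constrictions) == 1
        c = pg.constrictions[0]
        assert c.diameter == pytest.approx(10.0, abs=2 * grid.voxel_size)
        for p in pg.pores.values():
            assert p.diameter == pytest.approx(20.0, abs=2 * grid.voxel_size)

    def test_all_solid_grid_empty_graph(self):
        grid = VoxelGrid(np.ones((8, 8, 8), dtype=bool), 1.0)
        pg = extract_pore_graph(grid)
        assert len(pg) == 0 and len(pg.constrictions) == 0
        assert not pg.percolates()

    def test_pore_volumes_partition_fluid_volume(self, small_network):
        grid = voxelize(small_network, 5.0, resolution_guard=False)
        pg = extract_pore_graph(grid)
        total = sum(p.volume for p in pg.pores.values())
        fluid = (~grid.mask).sum() * grid.voxel_size**3
        assert total == pytest.approx(fluid, rel=1e-12)

    def test_constriction_never_wider_than_its_pores(self, small_network):
        """Constrictions are narrow passages between larger pores."""
        grid = voxelize(small_network, 2.5)
        pg = extract_pore_graph(grid)
        assert len(pg.constrictions) > 0
        for c in pg.constrictions:
            dmin = min(pg.pores[c.pore_a].diameter, pg.pores[c.pore_b].diameter)
            assert c.diameter <= dmin + 1e-9

    def test_percolation_matches_flood_fill(self, small_network):
        for grid in (
            voxelize(small_network, 5.0, resolution_guard=False),
            _two_cavity_grid(),
            fixture_geometry("sealed_cavity", 2.5),
        ):
            pg = extract_pore_graph(grid)
            labels, _ = ndi.label(~grid.mask)
            inlet = set(np.unique(labels[:, :, 0])) - {0}
            outlet = set(np.unique(labels[:, :, -1])) - {0}
            assert pg.percolates() == bool(inlet & outlet)

    def test_refinement_stability_on_fixture(self):
        coarse = _two_cavity_grid(h=2.0)
        fine = _two_cavity_grid(h=1.0)
        pg_c = extract_pore_graph(coarse)
        pg_f = extract_pore_graph(fine)
        assert abs(coarse.porosity - fine.porosity) < 0.02
        d_c = pg_c.constrictions[0].diameter
        d_f = pg_f.constrictions[0].diameter
        assert abs(d_c - d_f) <= 2.0  # one coarse voxel


class TestPathways:
    def test_through_hole_has_a_path(self):
        grid = fixture_geometry("tube", 2.5, radius=30.0, width=100.0, length=100.0)
        pg = extract_pore_graph(grid)
        (pid,) = pg.pores
        assert pg.through_path_count(pid) >= 1
        assert pg.obstruction_index(pid) == 0.0

    def test_sealed_cavity_is_fully_obstructed(self):
        grid = fixture_geometry("sealed_cavity", 2.5)
        pg = extract_pore_graph(grid)
        # the sealed pore is the one not touching either face
        sealed = [
            p.id for p in pg.pores.values()
            if not (p.touches_inlet or p.touches_outlet)
        ]
        assert sealed
        big = max(sealed, key=lambda pid: pg.pores[pid].volume)
        assert pg.through_path_count(big) == 0
        assert pg.obstruction_index(big) == 1.0

    def test_two_disjoint_necks_count_two_paths(self):
        # central cavity connected to each face by two separate narrow
        # channels, each ending in a wide vestibule at the face
        h, W, L = 1.0, 60.0, 80.0
        n = int(W / h)
        nz = int(L / h)
        xs = (np.arange(n) + 0.5) * h
        zs = (np.arange(nz) + 0.5) * h
        X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
        mask = np.ones((n, n, nz), dtype=bool)
        c, R = W / 2, 14.0
        mask[(X - c) ** 2 + (Y - c) ** 2 + (Z - L / 2) ** 2 <= R**2] = False
        for cx in (c - 9, c + 9):
            chan = (X - cx) ** 2 + (Y - c) ** 2
            mask[chan <= 3.0**2] = False
            mask[(chan <= 7.0**2) & ((Z <= L / 6) | (Z >= 5 * L / 6))] = False
        pg = extract_pore_graph(VoxelGrid(mask, h))
        cavity = max(pg.pores.values(), key=lambda p: p.volume)
        assert pg.through_path_count(cavity.id) == 2

    def test_obstruction_half_for_half_width_neck(self):
        D = 20.0
        grid = _capsule_with_neck(D=D, neck=D / 2)
        pg = extract_pore_graph(grid)
        cavity = max(pg.pores.values(), key=lambda p: p.volume)
        got = pg.obstruction_index(cavity.id)
        # one-voxel tolerance on both the bottleneck and the pore diameter
        h = grid.voxel_size
        lo = 1 - (D / 2 + h) / (D - h)
        hi = 1 - (D / 2 - h) / (D + h)
        assert lo <= got <= hi

    def test_widest_path_matches_voxel_bruteforce(self):
        """Threshold flood-fill over the voxel graph reproduces the
        graph-based widest-path bottleneck."""
        grid = _capsule_with_neck(D=24.0, neck=10.0)
        pg = extract_pore_graph(grid)
        cavity = max(pg.pores.values(), key=lambda p: p.volume)
        got = pg.widest_path_bottleneck(cavity.id)

        dt = ndi.distance_transform_edt(~grid.mask) * grid.voxel_size
        peak = np.unravel_index(
            np.argmax(np.where(pg.labels == cavity.id, dt, -1)), dt.shape
        )
        # brute force: largest tau such that {dt >= tau/2} connects both faces
        # through the cavity peak voxel
        best = 0.0
        for tau in np.unique(np.round(2 * dt[dt > 0], 6)):
            keep = dt >= tau / 2
            if not keep[peak]:
                continue
            lbl, _ = ndi.label(keep)
            if lbl[peak] in lbl[:, :, 0] and lbl[peak] in lbl[:, :, -1]:
                best = max(best, tau)
        assert got == pytest.approx(best, abs=2 * grid.voxel_size)

    def test_unknown_pore_id_raises(self):
        grid = fixture_geometry("tube", 2.5)
        pg = extract_pore_graph(grid)
        with pytest.raises(KeyError):
            pg.through_path_count(99)
        with pytest.raises(KeyError):
            pg.obstruction_index(99)

    def test_obstruction_report_schema(self, small_network):
        grid = voxelize(small_network, 5.0, resolution_guard=False)
        pg = extract_pore_graph(grid)
        rep = pg.obstruction_report()
        assert set(rep.columns) >= {
            "pore_id",
            "through_path_count",
            "obstruction_index",
            "bottleneck_diameter_nm",
        }
        assert ((rep.obstruction_index >= 0) & (rep.obstruction_index <= 1)).all()
        assert (rep.through_path_count >= 0).all()
        # pores with no pathway are fully obstructed
        blocked = rep.through_path_count == 0
        assert (rep.loc[blocked, "obstruction_index"] == 1.0).all()
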