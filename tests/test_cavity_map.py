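"""Void detection, consensus grids, symmetrisation, Monte-Carlo volumes and
lining polarity, validated against brute-force oracles and generator truth."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from chancav.cavities import (Cavity, VoidGrid, classify_cavities,
                              consensus_cavities, detect_voids, dilate_region,
                              mc_volume, polar_surface_fraction, symmetrize,
                              _DIRS)
from chancav.errors import PrecisionError, SamplingError
from chancav.model import Frame, Topology, Trajectory

from conftest import fast_spec


def _toy_topology(n, elements=None):
    elements = elements if elements is not None else ["C"] * n
    vdw = np.where(np.asarray(elements) == "O", 1.52, 1.7)
    return Topology(
        chain_ids=np.array(["A"] * n), resids=np.arange(1, n + 1),
        resnames=np.array(["ALA"] * n), names=np.array(["X"] * n),
        elements=np.asarray(elements, dtype="U2"), vdw_radii=vdw,
        species=np.array(["protein"] * n), molecule_ids=np.arange(n))


def _solid_block_with_hole(hole_radius=3.5, extent=10.0, spacing=1.4):
    """Cubic atom lattice with a central spherical void carved out.

    A spherical hole keeps atoms reachable within the 8 Å burial range
    along every scan direction (a large cubic carve would starve the
    diagonal rays, making the centre legitimately 'not buried')."""
    g = np.arange(-extent, extent + 1e-9, spacing)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = np.linalg.norm(pts, axis=1) < hole_radius + 3.1
    return pts[~inside]


def _brute_force_voids(coords, vdw, centers, probe=1.4, burial_range=8.0,
                       min_hits=9):
    """Independent re-evaluation of the void rule at given lattice points."""
    out = np.zeros(len(centers), bool)
    for i, c in enumerate(centers):
        d = np.linalg.norm(coords - c, axis=1)
        if np.any(d < vdw + probe):
            continue
        hits = 0
        for u in _DIRS:
            t = (coords - c) @ u
            perp2 = (np.linalg.norm(coords - c, axis=1) ** 2) - t ** 2
            if np.any((t > 0) & (t <= burial_range) & (perp2 <= vdw ** 2)):
                hits += 1
        out[i] = hits >= min_hits
    return out


@pytest.fixture(scope="module")
def block():
    coords = _solid_block_with_hole()
    topo = _toy_topology(len(coords))
    grid = VoidGrid(np.array([-8.0, -8.0, -8.0]), 1.0,
                    np.zeros((16, 16, 16), bool))
    vg = detect_voids(Frame(coords), topo, z_range=(-8.0, 8.0), grid=grid,
                      lumen_profile=(np.array([-8.0, 8.0]),
                                     np.array([np.nan, np.nan])))
    return coords, topo, vg


class TestDetectVoids:

    def test_center_of_closed_cavity_is_void(self, block):
        coords, topo, vg = block
        centre_idx = vg.index_of(np.zeros((1, 3)))[0]
        assert vg.data[tuple(centre_idx)]

    def test_exposed_point_is_not_void(self):
        """Clearance alone is not enough: an unburied point is not a void."""
        g = np.arange(-8.0, 8.1, 1.4)
        X, Y = np.meshgrid(g, g, indexing="ij")
        slab = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        topo = _toy_topology(len(slab))
        grid = VoidGrid(np.array([-4.0, -4.0, 0.0]), 1.0,
                        np.zeros((8, 8, 8), bool))
        vg = detect_voids(Frame(slab), topo, z_range=(0.0, 8.0), grid=grid,
                          lumen_profile=(np.array([0.0, 8.0]),
                                         np.array([np.nan, np.nan])))
        # points 4-7 Å above a flat slab keep clearance but see atoms in
        # at most half the scan directions
        assert not vg.data.any()

    def test_equals_brute_force_rule(self, block):
        """Every lattice decision equals an independent evaluation."""
        coords, topo, vg = block
        idx = np.indices(vg.shape).reshape(3, -1).T
        centers = vg.centers(idx)
        expected = _brute_force_voids(coords, topo.vdw_radii, centers)
        assert (vg.data.ravel() == expected).all()


class TestConsensus:
    def test_frequency_equals_mean_of_booleans(self, small_traj):
        spec, traj, truth = small_traj
        grid, comps = consensus_cavities(traj, stride_ns=10.0)
        from chancav.pore import align_to_pore_axis

        acc = np.zeros(grid.shape)
        n = 0
        for i in range(0, traj.n_frames, 10):
            fr, _, _ = align_to_pore_axis(traj.frame(i), traj.topology)
            vg = detect_voids(fr, traj.topology,
                              grid=VoidGrid(grid.origin, grid.spacing,
                                            np.zeros(grid.shape, bool)))
            acc += vg.data
            n += 1
        assert np.abs(grid.data - acc / n).max() == 0.0

    def test_stride_longer_than_trajectory_raises(self, small_traj):
        spec, traj, truth = small_traj
        with pytest.raises(SamplingError):
            consensus_cavities(traj, stride_ns=traj.n_frames * 2.0)

    def test_rare_cavity_excluded_at_threshold(self):
        """A voxel void in 1 of 10 sampled frames fails a 20% threshold."""
        g = VoidGrid(np.zeros(3), 1.0, np.zeros((3, 3, 3)))
        freq = np.zeros((3, 3, 3))
        freq[1, 1, 1] = 0.1
        mask = freq >= 0.20
        assert not mask.any()
        freq[1, 1, 1] = 0.3
        assert (freq >= 0.20).sum() == 1


class TestClassification:
    def test_generator_cavities_recovered(self, consensus_small):
        grid, comps, cavities, ref = consensus_small
        classes = sorted(c.cls for c in cavities)
        assert classes.count("intra") == 5
        assert classes.count("inter") == 5
        for c in cavities:
            if c.cls == "intra":
                assert len(c.chains) == 1
            elif c.cls == "inter":
                assert len(c.chains) == 2
                # adjacent chains around the pentamer
                i, j = sorted("ABCDE".index(x) for x in c.chains)
                assert (j - i) in (1, 4)

    def test_intra_sites_cover_all_subunits(self, consensus_small):
        grid, comps, cavities, ref = consensus_small
        intra_chains = sorted(c.chains[0] for c in cavities if c.cls == "intra")
        assert intra_chains == ["A", "B", "C", "D", "E"]


class TestSymmetrize:
    def test_full_turn_is_identity(self, consensus_small):
        grid, comps, cavities, ref = consensus_small
        from chancav.cavities import _rotate_voxels

        template = max((c for c in cavities if c.cls == "intra"),
                       key=lambda c: c.n_voxels)
        back = _rotate_voxels(template.voxels, grid, 360.0)
        orig = {tuple(v) for v in template.voxels}
        assert {tuple(v) for v in back} == orig

    def test_c5_symmetric_cavities_map_onto_each_other(self, consensus_small):
        grid, comps, cavities, ref = consensus_small
        regions = symmetrize(cavities, "intra", grid)
        assert sorted(regions) == [0, 1, 2, 3, 4]
        comp_sets = [{tuple(v) for v in c.voxels} for c in cavities
                     if c.cls == "intra"]
        for k, vox in regions.items():
            rot = {tuple(v) for v in vox}
            # the rotated template lands on exactly one detected cavity
            # (re-voxelisation after rotation erodes the boundary, so the
            # match is strong but not voxel-perfect; wrong sites overlap 0)
            overlaps = sorted((len(rot & s) / max(len(rot | s), 1)
                               for s in comp_sets), reverse=True)
            assert overlaps[0] > 0.6
            assert overlaps[1] == 0.0

    def test_missing_class_warns_and_returns_empty(self, consensus_small):
        grid, comps, cavities, ref = consensus_small
        only_intra = [c for c in cavities if c.cls == "intra"]
        with pytest.warns(UserWarning, match="no cavity"):
            out = symmetrize(only_intra, "inter", grid)
        assert out == {}


class TestMcVolume:
    def _grid(self, shape=(14, 14, 14), origin=(-7.0, -7.0, -7.0)):
        return VoidGrid(np.asarray(origin, float), 1.0, np.zeros(shape, bool))

    def _box_region(self, grid, half):
        idx = np.indices(grid.shape).reshape(3, -1).T
        centers = grid.centers(idx)
        return idx[np.all(np.abs(centers) < half, axis=1)]

    def test_declared_box_no_atoms(self):
        grid = self._grid()
        region = self._box_region(grid, 5.0)  # 10x10x10 box
        vol, se = mc_volume(region, grid, n=10_000, seed=1)
        assert abs(vol - 1000.0) <= 3 * se + 1e-9

    def test_empty_region_is_zero(self):
        grid = self._grid()
        vol, se = mc_volume(np.empty((0, 3), int), grid, n=1000, seed=0)
        assert vol == 0.0

    def test_too_few_iterations_rejected(self):
        grid = self._grid()
        with pytest.raises(PrecisionError):
            mc_volume(self._box_region(grid, 2.0), grid, n=50, seed=0)

    def test_sphere_carved_region_matches_quadrature(self):
        """Clearance-limited volume equals a 0.2 Å fine-grid integral."""
        grid = self._grid()
        region = self._box_region(grid, 6.0)
        # a shell of atoms at radius 4 + vdw + probe carves a 4 Å sphere
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(1200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = dirs * (4.0 + 3.1)
        topo = _toy_topology(len(coords))
        frame = Frame(coords)
        vol, se = mc_volume(region, grid, n=40_000, seed=3, frame=frame,
                            topology=topo)
        # quadrature at 0.2 Å on the same rule
        g = np.arange(-6.0, 6.0, 0.2) + 0.1
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        idx = np.floor((pts - grid.origin)).astype(int)
        keys = {tuple(v) for v in region}
        in_region = np.fromiter((tuple(i) in keys for i in idx), bool,
                                count=len(pts))
        d, _ = cKDTree(coords).query(pts, k=1)
        quad = ((d - 1.7 >= 1.4) & in_region).sum() * 0.2 ** 3
        assert abs(vol - quad) <= 3 * se + 0.2

    def _sphere_region(self, grid, radius):
        """A voxelised sphere: does not fill its bounding box, so the MC
        estimate carries real sampling noise (a full axis-aligned cube is
        exact by construction: every bounding-box sample is a hit)."""
        idx = np.indices(grid.shape).reshape(3, -1).T
        centers = grid.centers(idx)
        return idx[np.linalg.norm(centers, axis=1) < radius]

    def test_axis_aligned_cube_is_exact(self):
        grid = self._grid()
        region = self._box_region(grid, 3.6)
        vol, se = mc_volume(region, grid, n=1000, seed=0)
        assert vol == pytest.approx(float(len(region)))
        assert se == 0.0

    def test_unbiased_over_seeds(self):
        grid = self._grid()
        region = self._sphere_region(grid, 3.5)
        truth = float(len(region))  # union of unit voxel cubes
        vols, ses = [], []
        for s in range(50):
            v, e = mc_volume(region, grid, n=4000, seed=s)
            vols.append(v)
            ses.append(e)
        pooled_se = np.sqrt(np.mean(np.square(ses)) / 50)
        assert abs(np.mean(vols) - truth) <= 2 * pooled_se

    def test_se_scales_as_inverse_sqrt_n(self):
        grid = self._grid()
        region = self._sphere_region(grid, 3.5)
        _, se4 = mc_volume(region, grid, n=10_000, seed=2)
        _, se6 = mc_volume(region, grid, n=1_000_000, seed=2)
        assert se4 / se6 == pytest.approx(10.0, rel=0.20)

    def test_volume_monotone_in_declared_region(self):
        grid = self._grid()
        small = self._sphere_region(grid, 2.5)
        large = self._sphere_region(grid, 3.5)
        v_small, se_s = mc_volume(small, grid, n=20_000, seed=4)
        v_large, se_l = mc_volume(large, grid, n=20_000, seed=4)
        assert v_large >= v_small - 3 * (se_s + se_l + 1e-9)


class TestEndToEndVolumes:
    def test_generator_volumes_recovered(self, consensus_small, small_traj):
        """Declared box volumes within max(5%, 2 voxels) via dilated regions."""
        spec, traj, truth = small_traj
        grid, comps, cavities, ref = consensus_small
        for cls in ("intra", "inter"):
            true_v = truth.true_volumes[f"{cls}_0"]
            for k, vox in symmetrize(cavities, cls, grid).items():
                dil = dilate_region(vox, grid, 1)
                vol, se = mc_volume(dil, grid, n=20_000, seed=7 + k,
                                    frame=ref, topology=traj.topology)
                tol = max(0.05 * true_v, 2.0)
                assert abs(vol - true_v) <= tol + 3 * se, (cls, k, vol, true_v)


class TestPolarSurface:
    def _cavity_with_lining(self, elements):
        """A small cubic cavity lined by a shell of atoms."""
        from chancav.synthetic import CavitySite

        site = CavitySite("t", "intra", "box", 4.0, np.zeros(3), np.eye(3))
        anchors, dirs = site.shell_frame(1.2)
        vdw = np.where(np.asarray(elements([len(anchors)])) == "O", 1.52, 1.7)
        coords = anchors + (vdw + 1.4)[:, None] * dirs
        elems = np.where(vdw == 1.52, "O", "C")
        topo = _toy_topology(len(coords), elements=elems)
        grid = VoidGrid(np.array([-3.0, -3.0, -3.0]), 1.0,
                        np.zeros((6, 6, 6), bool))
        idx = np.indices(grid.shape).reshape(3, -1).T
        vox = idx[np.all(np.abs(grid.centers(idx)) < 2.0, axis=1)]
        cav = Cavity("t", "intra", ("A",), vox, grid,
                     lining_atoms=np.arange(len(coords)))
        return cav, Frame(coords), topo

    def test_carbon_only_lining_gives_zero(self):
        cav, fr, topo = self._cavity_with_lining(lambda n: np.array(["C"] * n[0]))
        assert polar_surface_fraction(cav, fr, topo) == pytest.approx(0.0)

    def test_oxygen_only_lining_gives_one(self):
        cav, fr, topo = self._cavity_with_lining(lambda n: np.array(["O"] * n[0]))
        assert polar_surface_fraction(cav, fr, topo) == pytest.approx(1.0)

    def test_mixed_lining_matches_dense_sampling(self):
        rng = np.random.default_rng(11)
        cav, fr, topo = self._cavity_with_lining(
            lambda n: np.where(rng.random(n[0]) < 0.4, "O", "C"))
        coarse = polar_surface_fraction(cav, fr, topo, n_points=240, seed=1)
        dense = polar_surface_fraction(cav, fr, topo, n_points=5000, seed=1)
        assert coarse == pytest.approx(dense, abs=0.08)
        assert 0.0 < dense < 1.0

    def test_empty_lining_is_missing(self):
        grid = VoidGrid(np.zeros(3), 1.0, np.zeros((2, 2, 2), bool))
        cav = Cavity("x", "intra", ("A",), np.array([[0, 0, 0]]), grid,
                     lining_atoms=np.array([], int))
        topo = _toy_topology(1)
        assert np.isnan(polar_surface_fraction(cav, Frame(np.zeros((1, 3))), topo))
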